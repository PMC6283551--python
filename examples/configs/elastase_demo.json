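{
  "seed": 43,
  "outdir": "scratch/elastase_demo",
  "model": {
    "p1_residues": "VAI"
  },
  "simulate": {
    "library_size": 100000,
    "rounds": 8,
    "carryover": 100000,
    "sample_size": 96
  }
}
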