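{
  "seed": 42,
  "outdir": "scratch/chymase_demo",
  "model": {
    "p1_residues": "FYW",
    "p2prime_acidic_mass": 0.5
  },
  "simulate": {
    "library_size": 100000,
    "rounds": 5,
    "carryover": 100000,
    "sample_size": 96
  }
}
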