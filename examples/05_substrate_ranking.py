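"""Rank recombinant substrates by cleavage efficiency from time courses.

Simulates fraction-cleaved time courses of linker substrates at the bench
time points (0/15/45/150 min), fits the first-order rate constant of each,
and reports the fold drop in efficiency versus the best substrate.
"""

from cleavemap import rank_efficiencies, simulate_timecourse

times = [0, 15, 45, 150]  # minutes
true_k = {"P1-Phe": 0.030, "P1-Trp": 0.030, "P1-Tyr": 0.024, "P1-Leu": 0.010}
courses = [
    simulate_timecourse(k, times, noise_sd=0.02, seed=i, substrate_id=sid)
    for i, (sid, k) in enumerate(true_k.items())
]

ranking = rank_efficiencies(courses)
print(ranking.table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print("\nfold_vs_best = k_best / k: the Leu substrate is cleaved about 3-fold "
      "more slowly than the aromatic-P1 substrates, while Phe/Trp/Tyr are "
      "within ~25% of each other.")
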