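# Methods

`cleavemap` implements the analysis chain used to map the extended cleavage
specificity of a protease from a cleavage-released substrate phage display
campaign, together with a simulator of such campaigns so that every stage can
be validated against planted ground truth. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## The display construct and subsite frame

Phage clones display a randomized nonamer insert in a fixed protein context,
`PGG(X)9HHHHHH`: a linker ending in Pro-Gly-Gly upstream and a C-terminal
His6 tag that tethers the phage to Ni-NTA beads. Proteolysis anywhere inside
the insert releases the phage; cleavage within the arms would not. Subsites
follow the Schechter-Berger convention — P1 immediately N-terminal of the
scissile bond, P1' immediately C-terminal — and the alignment frame spans
P5-P4' (nine subsites), while reported tables and logos default to P4-P4'
(`frames.ALIGNMENT_FRAME`, `frames.REPORT_FRAME`). When an anchored insert
does not cover the whole frame, outer subsites read the arm residues and are
flagged `arm_derived`; positions beyond even the arms are recorded as absent.

## Specificity model and biopanning simulator

Ground truth is an independent-subsite model: each subsite carries a
probability vector over the 20 residues, and a candidate site (P1 inside the
insert, P1 residue in the admissible set) is cleaved within one round with
probability `min(1, scale * prod(subsite weights))`. There are no pairwise
couplings — deliberately, because the downstream estimator is a positional
profile, which is exactly the class of models it can represent. Frame
positions outside the construct contribute a neutral factor (the subsite's
mean weight), so edge sites are neither favoured nor punished for context
that does not exist. A peptide's one-round cleavage probability combines its
sites as independent Bernoulli events, `1 - prod(1 - p_site)`; release adds a
nonspecific `background_release` (the protease-free control analog) as an
independent event.

Selection resamples a fixed number of phages (`carryover`) per round,
multinomially, with weights proportional to abundance times release
probability; the per-round enrichment is the pool's mean release probability
over background, the in silico analog of "phages released / PBS control". A
deterministic infinite-population recursion (`propagate_selection`) runs the
same dynamics on frequencies exactly and serves as a closed-form oracle for
the finite simulation.

Key defaults, with the reasoning:

* `background_release = 0.03`. Reported campaign-end enrichments of order
  15-100x over a protease-free control imply a nonspecific release a few
  percent of a saturated specific release.
* `saturation = 4.0` in `motif_model` (the unclipped cleavage probability of
  a consensus-matching site; the internal `site_efficiency_scale` is solved
  from it). A two-hour digestion with excess protease cleaves a consensus
  substrate essentially to completion while partially cleaving substrates
  that deviate at an informative subsite, so per-round discrimination is
  moderate and a multi-round campaign approximately preserves the planted
  subsite composition in the selected pool instead of collapsing onto the
  single best sequence. The value was fixed by calibrating the full
  chain — selection, clone sampling, anchored alignment, profile — so that
  the recovered P2' acidity of a planted model is approximately unbiased;
  that calibration is part of the simulator's design, done once, and is what
  makes "recover the planted weights" a meaningful test at all. Stronger
  saturation flattens discrimination (profiles drift toward background);
  weaker saturation exaggerates it (profiles overshoot the planted
  preference).
* Campaign shape: library 1e5 clones, 5 rounds, carryover 1e5, 96 sequenced
  clones. The clone counts and round numbers mirror the bench campaign; the
  library and carryover are scaled down from the physical 5e7-clone library
  and ~1e9 pfu per round so that a full 20-replicate recovery study runs in
  minutes on one CPU. The scaled-down pool keeps the same qualitative regime
  (selection far from mutation-limited, duplicates appearing among 96
  sampled clones after selection but not before).
* Kinetic time courses follow `f(t) = 1 - exp(-k t)` with additive Gaussian
  noise clipped to [0, 1]; absorbance traces are `baseline + amplitude * f`.
  The default panel times extend to 360 min (the "up to 6 h" monitoring
  window); validation substrates use the bench time points 0/15/45/150 min.

## Panel kinetics and P1 calling

Initial rates are ordinary least-squares slopes over the earliest points —
those within 20% (`window_fraction`) of the total signal rise, minimum
three points — clipped at zero. The estimator is invariant to baseline
shifts and scales linearly with amplitude. A residue enters the P1 candidate
set when its best substrate reaches 20% of the panel maximum
(`threshold = 0.2`); the data this mirrors show order-of-magnitude contrast
between cleaved and uncleaved substrates, so the call is insensitive to the
exact cut-off over a wide range, and the threshold is exposed in config.
Primary specificity labels follow the P1 group: chymotryptic (F/Y/W, Leu
admitted), elastolytic (A/V/I, Leu admitted), tryptic (K/R), asp-ase (D/E),
otherwise mixed. Leu is deliberately ambiguous — mast cell chymases commonly
cleave Leu-P1 substrates even when a chromogenic Leu substrate is not
cleaved, and the two readouts (chromogenic panel, recombinant substrates)
are reported side by side rather than merged.

Rate constants for fraction-cleaved courses are fitted by bracketing the
1-D residual sum of squares on a 200-point log grid and refining with
bounded scalar minimization (`xatol = 1e-12`), which is deterministic,
needs no starting guess, and recovers noiseless rates to better than four
significant digits for `k*t_max` between 0.1 and 5. Efficiency rankings
report `fold_vs_best = k_best / k`; a substrate with `k = 0` is flagged
`undetectable` rather than given an infinite fold.

## Anchored alignment

The alignment reproduces, as a deterministic algorithm, the manual
procedure used with phage display data: inserts with exactly one P1
candidate are anchored first; inserts with several candidates are placed to
fit the emerging profile. Concretely:

* The positional profile adds a pseudocount of 0.5 per residue per subsite
  and, by default, counts only insert residues (`arm_policy="mask"`),
  because arm residues reflect the construct — the Pro-Gly-Gly arm otherwise
  inflates upstream Gly. `include` is available for figure-style tables.
  Duplicate clones count by multiplicity by default; `unique` mode is
  provided.
* Placement maximizes the joint log-likelihood of the assignment under its
  own smoothed profile. Frame positions excluded from the profile (masked
  arm residues, absent positions) are scored with a background distribution
  (uniform by default, empirical composition available): without this,
  placements overlapping the arms would be favoured simply for having fewer
  scored subsites, and anchors drift to the insert edges.
* The optimizer is coordinate ascent with exact single-peptide moves,
  escalated to joint two-peptide moves when single moves stall, from the
  profile-seeded start plus seven hash-seeded restarts (restart
  initialization depends only on each peptide's sequence, so results are
  invariant to input order). For small ambiguous sets every restart is
  polished with pair moves; for large ones (> 30 ambiguous peptides, where
  the anchor profile is informative and restarts converge to one basin) the
  quadratic pair phase runs on the best restart only. A converged
  assignment is optimal against every one- and two-peptide re-placement,
  and on random instances small enough to enumerate (12 peptides, up to 3
  sites each) it matches the exhaustive joint optimum.
* Ties break toward the smaller (more N-terminal) P1 offset. The likelihood
  trace is non-decreasing by construction; non-convergence within
  `max_iter = 50` passes is warned about and the last state returned.
* `score_offset` (the log-odds of one placement against a background,
  excluding the constrained P1 subsite) is exposed as a diagnostic for
  inspecting individual placements; the iteration itself uses the joint
  likelihood above so that its objective is the one being monotonically
  improved.

## Reporting layer

Two residue groupings coexist, as in the source convention: a six-class
chemical grouping for percentage tables (aromatic FYW; acidic DE; basic KR;
small aliphatic GA; large aliphatic VLIP; hydrophilic STHNQCM) and a
five-colour logo scheme (KRH yellow, DE red, FYW green, STCMNQ white,
GAVLIP blue). His is hydrophilic in the grouping but coloured with the
basics in logos; the inconsistency is inherited deliberately and the two
are kept as distinct named schemes. Logos are probability-unit (not
information-content) matrices; an optional matplotlib renderer draws
stacked-letter logos, and the matrix TSV is consumable by standard logo
tools. Profile comparisons use per-subsite Jensen-Shannon divergence, base
2, which is symmetric and bounded in [0, 1]. The consensus string shows a
residue at 50% dominance, a lowercase class initial at 50% class dominance,
else `x`.

## What the synthetic data do and do not show

The simulator emulates cleavage-driven selection with independent subsites,
perfect sequencing, and no phage biology: no amplification bias or burst
size variation, no binding-chemistry effects, no PCR or sequencing errors,
and no epistasis between subsites. Passing recovery tests therefore shows
that the analysis chain is a consistent estimator of positional preferences
when positional preferences are the truth — it does not show robustness to
coupled subsites or amplification artifacts in real campaigns. The P1
candidate set is an input (from the chromogenic panel), not discovered from
the peptides; a wrong panel call propagates to the alignment by design,
since that matches how the bench procedure anchors its alignments.

## Degenerate inputs and numerical conventions

Profiles from empty alignments, empty P1 candidate sets, all-zero kinetic
panels, rankings where nothing is cleaved, and selection rounds with
all-zero weights raise informative errors rather than returning silent
defaults (the zero-rate panel warns and returns an empty candidate set,
which classifies as "undetermined"). Probability columns are validated to
sum to 1 within 1e-9. Artifact writers emit full-precision floats
(`repr`) and readers parse with round-trip precision, so write-then-read
is exact and two runs with the same config and seed produce byte-identical
artifacts (verified by SHA-256 in the run report). All randomness flows
through explicit integer seeds via `numpy.random.default_rng`; no global
RNG state is used.

## Problem sizes used in validation

The test suite and the acceptance script validate at: 100 random alignment
instances of 12 peptides against exhaustive enumeration; 20 replicates of
the full campaign (library 1e5, 5 rounds, 96 clones) per planted model; 40
replicates of a 2000-clone planted-prevalence oracle; 200 replicates of
noisy kinetic fits. These sizes are the package's validation defaults and
complete in a few minutes on one CPU.
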