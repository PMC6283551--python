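"""Synthetic substrate phage display: library generation, biopanning, kinetics.

Ground truth is an independent-subsite specificity model: each subsite of a
P5-P4' frame carries a probability vector over the 20 residues, and the
per-round cleavage probability of a candidate site is a scaled product of the
weights of the residues it presents. Cleavage-driven selection then mirrors
the bench protocol: phages tethered by a C-terminal His6 tag are released
when the protease cuts inside the displayed insert, released phages seed the
next round, and after the final round a small number of clones is sequenced.

Everything stochastic takes an explicit integer seed; no global RNG state is
touched, so every simulation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import ALIGNMENT_FRAME, SubsiteFrame
from .kinetics import TimeCourse
from .peptides import (
    AA_INDEX,
    AMINO_ACIDS,
    DisplayContext,
    Peptide,
    decode,
    encode,
    encode_peptides,
    merge_peptides,
)

__all__ = [
    "SpecificityModel",
    "BiopanningResult",
    "motif_model",
    "generate_library",
    "site_probabilities",
    "cleavage_probability",
    "release_probability",
    "simulate_biopanning",
    "propagate_selection",
    "sample_clones",
    "simulate_timecourse",
    "simulate_panel",
    "DEFAULT_PANEL",
]


@dataclass(frozen=True)
class SpecificityModel:
    """Ground-truth extended specificity used to drive selection.

    ``subsite_weights`` maps each subsite label of ``frame`` to a 20-vector of
    residue probabilities (indexed like :data:`~cleavemap.peptides.AMINO_ACIDS`).
    A candidate site's one-round cleavage probability is
    ``min(1, site_efficiency_scale * prod(weights))``; sites whose P1 residue
    is not in ``admissible_p1`` are never cleaved. ``background_release`` is
    the nonspecific per-round release probability of any phage, the analog of
    the protease-free PBS control.
    """

    subsite_weights: dict[str, np.ndarray]
    admissible_p1: frozenset[str]
    site_efficiency_scale: float
    background_release: float = 0.03
    frame: SubsiteFrame = ALIGNMENT_FRAME

    def __post_init__(self) -> None:
        for label in self.frame.labels:
            if label not in self.subsite_weights:
                raise ValueError(f"missing weights for subsite {label}")
            w = np.asarray(self.subsite_weights[label], dtype=float)
            if w.shape != (20,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"subsite {label}: weights must be a 20-vector summing to 1 "
                    f"(sum={w.sum():.6g})"
                )
            self.subsite_weights[label] = w
        if self.site_efficiency_scale <= 0:
            raise ValueError("site_efficiency_scale must be positive")
        if not 0 <= self.background_release < 1:
            raise ValueError("background_release must lie in [0, 1)")
        bad = sorted(self.admissible_p1 - set(AMINO_ACIDS))
        if bad:
            raise ValueError(f"non-standard residues in admissible_p1: {bad}")

    def weight_matrix(self) -> np.ndarray:
        """(n_subsites, 20) weight matrix in frame order."""
        return np.stack([self.subsite_weights[lab] for lab in self.frame.labels])


def motif_model(
    p1_residues: str,
    *,
    p1_weights: np.ndarray | None = None,
    p2prime_acidic_mass: float | None = None,
    background_release: float = 0.03,
    saturation: float = 4.0,
    frame: SubsiteFrame = ALIGNMENT_FRAME,
) -> SpecificityModel:
    """Build a chymase/elastase-style planted model.

    P1 weight is spread over ``p1_residues`` (uniformly unless ``p1_weights``
    is given); optionally a P2' preference for Asp/Glu carrying total
    probability ``p2prime_acidic_mass``; every other subsite is uniform.

    ``saturation`` sets how strongly a consensus-matching site is cleaved in
    one round: the scale is chosen so that the best possible site has an
    unclipped cleavage probability of ``saturation`` (clipped to 1), i.e. a
    consensus site is cut with near certainty within one digestion, while
    sites deviating at an informative subsite remain partially cleaved. This
    keeps per-round discrimination moderate, as in a to-completion digestion,
    so selected pools reflect the planted weights rather than collapsing onto
    the single best sequence.
    """
    weights: dict[str, np.ndarray] = {}
    for label in frame.labels:
        weights[label] = np.full(20, 1.0 / 20)
    p1 = np.zeros(20)
    if p1_weights is None:
        for r in p1_residues:
            p1[AA_INDEX[r]] = 1.0 / len(p1_residues)
    else:
        p1_weights = np.asarray(p1_weights, dtype=float)
        for r, w in zip(p1_residues, p1_weights):
            p1[AA_INDEX[r]] = w / p1_weights.sum()
    weights["P1"] = p1
    if p2prime_acidic_mass is not None:
        p2p = np.full(20, (1.0 - p2prime_acidic_mass) / 18)
        p2p[AA_INDEX["D"]] = p2prime_acidic_mass / 2
        p2p[AA_INDEX["E"]] = p2prime_acidic_mass / 2
        weights["P2'"] = p2p
    best = np.prod([weights[lab].max() for lab in frame.labels])
    return SpecificityModel(
        subsite_weights=weights,
        admissible_p1=frozenset(p1_residues),
        site_efficiency_scale=saturation / best,
        background_release=background_release,
        frame=frame,
    )


@dataclass(frozen=True)
class BiopanningResult:
    """Outcome of a multi-round cleavage-driven selection.

    ``per_round_libraries[r]`` is the phage pool after round ``r`` (merged
    unique peptides with counts); ``per_round_enrichment[r]`` is the mean
    release probability of the pool entering round ``r`` divided by the
    background release, the in silico analog of "released phages over PBS
    control". ``sampled_clones`` holds the sequenced clones, if sampling was
    requested.
    """

    per_round_libraries: list[list[Peptide]]
    per_round_enrichment: list[float]
    sampled_clones: list[Peptide] = field(default_factory=list)


def generate_library(
    n_clones: int,
    context: DisplayContext = DisplayContext(),
    composition: np.ndarray | str = "uniform",
    seed: int = 0,
) -> list[Peptide]:
    """Draw a random-insert phage library.

    Residues are drawn i.i.d. per position from ``composition`` (a 20-vector
    of probabilities, or ``"uniform"``); identical inserts are merged with
    summed multiplicities.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1; an empty library cannot be panned")
    if isinstance(composition, str):
        if composition != "uniform":
            raise ValueError(f"unknown composition {composition!r}")
        p = np.full(20, 1.0 / 20)
    else:
        p = np.asarray(composition, dtype=float)
        if p.shape != (20,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"composition must be a 20-vector of probabilities summing to 1 "
                f"(sum={p.sum():.6g})"
            )
    rng = np.random.default_rng(seed)
    codes = rng.choice(20, size=(n_clones, context.insert_length), p=p)
    uniq, counts = np.unique(codes, axis=0, return_counts=True)
    return merge_peptides(
        [Peptide(decode(row), int(c)) for row, c in zip(uniq, counts)]
    )


def _site_probability_matrix(
    codes: np.ndarray, context: DisplayContext, model: SpecificityModel
) -> np.ndarray:
    """(n_peptides, insert_length) per-site cleavage probabilities.

    Site *o* places P1 on insert position *o*; flanking subsites read into the
    display arms. Subsites that fall outside even the arms contribute a
    neutral factor (the mean weight of that subsite, i.e. the expectation over
    a uniform residue), so edge sites are neither favoured nor punished for
    unobservable context.
    """
    n, L = codes.shape
    up = encode(context.upstream_arm)
    down = encode(context.downstream_arm)
    pad = np.concatenate(
        [np.tile(up, (n, 1)), codes, np.tile(down, (n, 1))], axis=1
    )
    total = pad.shape[1]
    W = model.weight_matrix()
    neutral = W.mean(axis=1)
    p1j = model.frame.p1_index
    probs = np.empty((n, L))
    for o in range(L):
        prod = np.ones(n)
        for j in range(len(model.frame)):
            pos = up.size + o + (j - p1j)
            if 0 <= pos < total:
                prod *= W[j, pad[:, pos]]
            else:
                prod *= neutral[j]
        probs[:, o] = np.minimum(1.0, model.site_efficiency_scale * prod)
    admissible = np.array([aa in model.admissible_p1 for aa in AMINO_ACIDS])
    probs[~admissible[codes]] = 0.0
    return probs


def site_probabilities(
    peptide: Peptide, context: DisplayContext, model: SpecificityModel
) -> np.ndarray:
    """Per-offset one-round cleavage probabilities for a single peptide."""
    return _site_probability_matrix(
        encode(peptide.sequence)[None, :], context, model
    )[0]


def cleavage_probability(
    peptide: Peptide, context: DisplayContext, model: SpecificityModel
) -> float:
    """Probability that at least one site in the insert is cleaved in one round.

    Sites are treated as independent Bernoulli events:
    ``1 - prod_sites(1 - p_site)``. Background release is not included here;
    see :func:`release_probability`.
    """
    p = site_probabilities(peptide, context, model)
    return float(1.0 - np.prod(1.0 - p))


def release_probability(
    peptide: Peptide, context: DisplayContext, model: SpecificityModel
) -> float:
    """One-round release probability: specific cleavage or nonspecific release."""
    c = cleavage_probability(peptide, context, model)
    return float(1.0 - (1.0 - c) * (1.0 - model.background_release))


def _release_vector(
    codes: np.ndarray, context: DisplayContext, model: SpecificityModel
) -> np.ndarray:
    p = _site_probability_matrix(codes, context, model)
    c = 1.0 - np.prod(1.0 - p, axis=1)
    return 1.0 - (1.0 - c) * (1.0 - model.background_release)


def simulate_biopanning(
    library: list[Peptide],
    model: SpecificityModel,
    rounds: int,
    carryover: int,
    seed: int,
    *,
    context: DisplayContext = DisplayContext(),
    sample_size: int | None = None,
) -> BiopanningResult:
    """Finite-population, multinomially resampled selection.

    Each round draws ``carryover`` phages from the current pool with weights
    proportional to abundance times one-round release probability (specific
    cleavage plus background). Enrichment is recorded as the pool's mean
    release probability over the background release.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if carryover < 1:
        raise ValueError("carryover must be >= 1")
    rng = np.random.default_rng(seed)
    codes, counts = encode_peptides(library)
    libraries: list[list[Peptide]] = []
    enrichments: list[float] = []
    for r in range(1, rounds + 1):
        rel = _release_vector(codes, context, model)
        mean_release = float((counts * rel).sum() / counts.sum())
        enrichments.append(
            mean_release / model.background_release
            if model.background_release > 0
            else float("nan")
        )
        weights = counts * rel
        wsum = weights.sum()
        if wsum == 0:
            raise ValueError(
                f"round {r}: all selection weights are zero "
                "(no cleavable site and no background release)"
            )
        new_counts = rng.multinomial(carryover, weights / wsum)
        keep = new_counts > 0
        codes, counts = codes[keep], new_counts[keep].astype(float)
        libraries.append(
            merge_peptides(
                [Peptide(decode(row), int(c)) for row, c in zip(codes, counts)]
            )
        )
    sampled: list[Peptide] = []
    if sample_size is not None:
        sampled = sample_clones(
            libraries[-1], sample_size, int(rng.integers(2**31))
        )
    return BiopanningResult(libraries, enrichments, sampled)


def propagate_selection(
    library: list[Peptide],
    model: SpecificityModel,
    rounds: int,
    *,
    context: DisplayContext = DisplayContext(),
) -> tuple[list[str], np.ndarray, list[float]]:
    """Infinite-population (deterministic) selection recursion.

    Frequencies evolve exactly as ``f' = f * release / sum(f * release)``.
    Returns unique sequences, a ``(rounds + 1, n)`` frequency matrix whose
    first row is the input composition, and per-round enrichments. This is
    the closed-form limit against which the finite multinomial simulation can
    be checked.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    codes, counts = encode_peptides(library)
    rel = _release_vector(codes, context, model)
    freqs = np.empty((rounds + 1, counts.size))
    freqs[0] = counts / counts.sum()
    enrichments = []
    for r in range(rounds):
        mean_release = float(freqs[r] @ rel)
        enrichments.append(
            mean_release / model.background_release
            if model.background_release > 0
            else float("nan")
        )
        w = freqs[r] * rel
        if w.sum() == 0:
            raise ValueError(f"round {r + 1}: all selection weights are zero")
        freqs[r + 1] = w / w.sum()
    return [decode(row) for row in codes], freqs, enrichments


def sample_clones(final_library: list[Peptide], n: int, seed: int) -> list[Peptide]:
    """Sample *n* clones with replacement and merge duplicates.

    Mirrors picking plaques after the last round and sequencing ~96 of them:
    identical inserts appear as one record with summed multiplicity.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if not final_library:
        raise ValueError("cannot sample clones from an empty library")
    rng = np.random.default_rng(seed)
    counts = np.array([p.multiplicity for p in final_library], dtype=float)
    draws = rng.multinomial(n, counts / counts.sum())
    return merge_peptides(
        [
            Peptide(p.sequence, int(d))
            for p, d in zip(final_library, draws)
            if d > 0
        ]
    )


def simulate_timecourse(
    k: float,
    times: np.ndarray,
    noise_sd: float,
    seed: int,
    *,
    substrate_id: str = "sim",
    kind: str = "fraction",
    baseline: float = 0.0,
    amplitude: float = 1.0,
) -> TimeCourse:
    """Simulate a first-order cleavage time course.

    Fraction cleaved follows ``f(t) = 1 - exp(-k t)`` with additive Gaussian
    noise truncated to [0, 1] by clipping. With ``kind="absorbance"`` the
    returned values are ``baseline + amplitude * f``, emulating an A405 trace.
    """
    if k < 0:
        raise ValueError("rate constant k must be >= 0")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    rng = np.random.default_rng(seed)
    f = 1.0 - np.exp(-k * times)
    if noise_sd > 0:
        f = np.clip(f + rng.normal(0.0, noise_sd, size=times.shape), 0.0, 1.0)
    if kind == "fraction":
        return TimeCourse(substrate_id, times, f, "fraction")
    if kind == "absorbance":
        return TimeCourse(substrate_id, times, baseline + amplitude * f, "absorbance")
    raise ValueError(f"unknown kind {kind!r}")


#: Chromogenic panel layout: substrate id -> P1 residue. Covers chymase (F, Y,
#: W, L), elastase (V, A, I), tryptase (K, R) and asp-ase (D) substrates.
DEFAULT_PANEL: dict[str, str] = {
    "chym-F": "F",
    "chym-Y": "Y",
    "chym-W": "W",
    "chym-L": "L",
    "elas-V": "V",
    "elas-A": "A",
    "elas-I": "I",
    "tryp-K": "K",
    "tryp-R": "R",
    "asp-D": "D",
}


def simulate_panel(
    model: SpecificityModel,
    times: np.ndarray,
    noise_sd: float,
    seed: int,
    *,
    panel: dict[str, str] | None = None,
    k_max: float = 0.02,
    baseline: float = 0.05,
    amplitude: float = 1.0,
) -> tuple[list[TimeCourse], dict[str, str]]:
    """Simulate an A405 chromogenic panel from the ground-truth model.

    Each substrate's hydrolysis rate scales with the model's P1 weight for its
    reporter residue (``k_max`` for the preferred residue); inadmissible P1
    residues give flat background traces. Returns the time courses and the
    substrate -> P1 map needed by :func:`~cleavemap.kinetics.analyze_panel`.
    """
    panel = dict(panel) if panel is not None else dict(DEFAULT_PANEL)
    w = model.subsite_weights["P1"]
    wmax = w.max()
    rng = np.random.default_rng(seed)
    courses = []
    for sid, res in panel.items():
        k = k_max * w[AA_INDEX[res]] / wmax if res in model.admissible_p1 else 0.0
        courses.append(
            simulate_timecourse(
                k,
                times,
                noise_sd,
                int(rng.integers(2**31)),
                substrate_id=sid,
                kind="absorbance",
                baseline=baseline,
                amplitude=amplitude,
            )
        )
    return courses, panel
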