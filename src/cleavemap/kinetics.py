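"""Kinetic readouts: chromogenic-panel P1 calling and substrate efficiency ranking.

Two kinds of time series are handled:

* absorbance traces from p-nitroanilide (pNA) substrate hydrolysis monitored
  at 405 nm, one substrate per P1 residue, used to call the primary (P1)
  specificity of a protease;
* fraction-cleaved time courses of recombinant linker substrates, fitted to a
  single-exponential ``f(t) = 1 - exp(-k t)`` to rank cleavage efficiencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .peptides import AMINO_ACIDS

__all__ = [
    "TimeCourse",
    "PanelResult",
    "P1CandidateSet",
    "EfficiencyRanking",
    "RateFit",
    "estimate_initial_rate",
    "analyze_panel",
    "call_p1_candidates",
    "classify_primary_specificity",
    "fit_rate_constant",
    "rank_efficiencies",
]

#: P1 residue groups used to label primary specificity.
SPECIFICITY_GROUPS: dict[str, frozenset[str]] = {
    "chymotryptic": frozenset("FYWL"),
    "elastolytic": frozenset("AVIL"),
    "tryptic": frozenset("KR"),
    "asp-ase": frozenset("DE"),
}


@dataclass(frozen=True)
class TimeCourse:
    """A single substrate's signal versus time.

    ``value_kind`` distinguishes raw A405 absorbance from fraction cleaved
    (which must lie in [0, 1]).
    """

    substrate_id: str
    times: np.ndarray
    values: np.ndarray
    value_kind: str = "absorbance"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.value_kind not in ("absorbance", "fraction"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.times.shape != self.values.shape or self.times.size < 2:
            raise ValueError(
                f"{self.substrate_id}: need >= 2 paired (time, value) points"
            )
        if (self.times < 0).any() or (np.diff(self.times) <= 0).any():
            raise ValueError(
                f"{self.substrate_id}: times must be non-negative and strictly increasing"
            )
        if self.value_kind == "fraction" and (
            (self.values < 0).any() or (self.values > 1).any()
        ):
            raise ValueError(f"{self.substrate_id}: fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return self.times.size


def estimate_initial_rate(tc: TimeCourse, window_fraction: float = 0.2) -> float:
    """Initial hydrolysis rate (signal units per minute).

    Fits an ordinary least-squares line to the earliest points, those within
    ``window_fraction`` of the total signal rise above the first point, always
    keeping at least three points. The rate is clipped at zero: a decaying
    baseline is read as "no activity", not negative activity.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    t, v = tc.times, tc.values
    if t.size < 3:
        raise ValueError(
            f"{tc.substrate_id}: fewer than 3 points; record more time points or "
            "use a larger window"
        )
    rise = v.max() - v[0]
    if rise <= 0:
        return 0.0  # no signal increase at all
    else:
        above = np.nonzero(v - v[0] > window_fraction * rise)[0]
        n = int(above[0]) if above.size else t.size
        n = max(n, 3)
    slope = np.polyfit(t[:n], v[:n], 1)[0]
    return float(max(slope, 0.0))


@dataclass(frozen=True)
class PanelResult:
    """Per-substrate activities from a chromogenic panel.

    ``table`` columns: substrate_id, p1_residue, initial_rate,
    relative_activity (fraction of the panel maximum).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"substrate_id", "p1_residue", "initial_rate", "relative_activity"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")


def analyze_panel(
    courses: Sequence[TimeCourse],
    p1_residues: Mapping[str, str],
    window_fraction: float = 0.2,
) -> PanelResult:
    """Estimate initial rates for every panel substrate and normalize to the max.

    *p1_residues* maps substrate_id to the P1 residue of that substrate.
    """
    if not courses:
        raise ValueError("empty panel")
    rows = []
    for tc in courses:
        rate = estimate_initial_rate(tc, window_fraction)
        rows.append((tc.substrate_id, p1_residues[tc.substrate_id], rate))
    df = pd.DataFrame(rows, columns=["substrate_id", "p1_residue", "initial_rate"])
    rmax = df["initial_rate"].max()
    df["relative_activity"] = df["initial_rate"] / rmax if rmax > 0 else 0.0
    return PanelResult(df)


@dataclass(frozen=True)
class P1CandidateSet:
    """Residues accepted as candidate P1 anchors, with provenance."""

    residues: frozenset[str]
    threshold_used: float
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = sorted(self.residues - set(AMINO_ACIDS))
        if bad:
            raise ValueError(f"non-standard residues in P1 set: {bad}")

    def __iter__(self):
        return iter(sorted(self.residues))


def call_p1_candidates(panel: PanelResult, threshold: float = 0.2) -> P1CandidateSet:
    """Call the P1 residue set from panel relative activities.

    A residue is called when its best substrate reaches ``threshold`` of the
    panel maximum. The default 0.2 cleanly separates "cleaved efficiently"
    from "not cleaved" in chymase/elastase panels.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    df = panel.table
    best = df.groupby("p1_residue")["relative_activity"].max()
    residues = frozenset(best.index[best >= threshold])
    if df["initial_rate"].max() == 0:
        warnings.warn("all panel rates are zero; P1 candidate set is empty")
        residues = frozenset()
    return P1CandidateSet(residues, threshold, provenance="chromogenic panel")


def classify_primary_specificity(p1: P1CandidateSet) -> str:
    """Label the primary specificity implied by a P1 candidate set.

    Leu is accepted in both the chymotryptic and elastolytic groups because
    mast cell chymases commonly cleave after Leu; a set containing only
    residues of one group gets that group's label, anything else is "mixed".
    """
    if not p1.residues:
        return "undetermined"
    for label, group in SPECIFICITY_GROUPS.items():
        if p1.residues <= group:
            return label
    return "mixed"


@dataclass(frozen=True)
class RateFit:
    """First-order rate constant fit with its residual sum of squares."""

    k: float
    rss: float


def _rss(k: float, t: np.ndarray, v: np.ndarray) -> float:
    return float(np.sum((1.0 - np.exp(-k * t) - v) ** 2))


def fit_rate_constant(tc: TimeCourse) -> RateFit:
    """Least-squares fit of ``f(t) = 1 - exp(-k t)`` to a fraction-cleaved course.

    The 1-D objective is bracketed on a log-spaced grid and refined by bounded
    scalar minimization, so the fit is deterministic and needs no starting
    guess. ``k`` is constrained to be non-negative; an all-zero course gives
    ``k = 0`` exactly.
    """
    if tc.value_kind != "fraction":
        raise ValueError(f"{tc.substrate_id}: fit_rate_constant needs fraction-cleaved values")
    t, v = tc.times, tc.values
    if not v.any():
        return RateFit(0.0, 0.0)
    tmax = t.max()
    grid = np.logspace(np.log10(1e-4 / tmax), np.log10(50.0 / tmax), 200)
    losses = np.array([_rss(k, t, v) for k in grid])
    i = int(losses.argmin())
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        _rss, bounds=(lo, hi), args=(t, v), method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(
            f"{tc.substrate_id}: rate fit did not converge; best grid value k={grid[i]:.6g}"
        )
    if _rss(0.0, t, v) <= res.fun:
        return RateFit(0.0, _rss(0.0, t, v))
    return RateFit(float(res.x), float(res.fun))


@dataclass(frozen=True)
class EfficiencyRanking:
    """Substrates ordered by rate constant with fold drop versus the best.

    ``table`` columns: substrate_id, k, fold_vs_best, undetectable (True when
    ``k = 0`` so the fold ratio is undefined).
    """

    table: pd.DataFrame


def rank_efficiencies(courses: Sequence[TimeCourse]) -> EfficiencyRanking:
    """Fit every course and rank substrates by cleavage efficiency.

    ``fold_vs_best = k_best / k`` is 1 for the most efficiently cleaved
    substrate and grows as efficiency drops; uncleaved substrates (k = 0) are
    flagged rather than given an infinite fold.
    """
    if len(courses) < 2:
        raise ValueError("ranking needs at least 2 substrates")
    fits = [(tc.substrate_id, fit_rate_constant(tc).k) for tc in courses]
    kbest = max(k for _, k in fits)
    if kbest == 0:
        raise ValueError("all rate constants are zero; nothing to rank")
    rows = []
    for sid, k in sorted(fits, key=lambda x: (-x[1], x[0])):
        rows.append((sid, k, kbest / k if k > 0 else np.inf, k == 0))
    return EfficiencyRanking(
        pd.DataFrame(rows, columns=["substrate_id", "k", "fold_vs_best", "undetectable"])
    )
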