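"""P1-anchored alignment of selected nonamers into a subsite frame.

This reproduces, as a deterministic algorithm, the manual consensus-building
procedure used with substrate phage display data: every selected insert is
anchored so that a residue from the P1 candidate set (called from the
chromogenic panel) sits at the P1 position of a fixed P5-P4' frame. Inserts
with exactly one candidate residue are anchored first and define an initial
positional profile; inserts with several candidate residues ("more than one
possible cleavage site") are then placed at the offset that best fits the
emerging profile, iterating until the assignment is stable.

Positions of the frame that fall outside the nonamer insert are filled from
the fixed display arms (``PGG`` upstream, His6 downstream) and flagged as
arm-derived; by default they are excluded from profiles, because arm residues
reflect the construct, not the protease - e.g. the Gly excess upstream of the
cut contributed by the ``...PGG`` arm.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .frames import ALIGNMENT_FRAME, SubsiteFrame
from .kinetics import P1CandidateSet
from .peptides import AA_INDEX, AMINO_ACIDS, DisplayContext, Peptide

__all__ = [
    "FrameResidue",
    "AlignedPeptide",
    "PositionalProfile",
    "IterativeAlignmentResult",
    "enumerate_sites",
    "place_peptide",
    "align_unambiguous",
    "build_profile",
    "empirical_background",
    "score_offset",
    "total_log_likelihood",
    "resolve_and_iterate",
]


@dataclass(frozen=True)
class FrameResidue:
    """Residue occupying one subsite of an aligned peptide.

    ``residue`` is ``None`` when the subsite falls outside even the display
    arms; ``arm_derived`` marks residues read from the fixed arms rather than
    the randomized insert.
    """

    subsite: str
    residue: str | None
    arm_derived: bool = False


@dataclass(frozen=True)
class AlignedPeptide:
    """A peptide anchored at a chosen cleavage offset.

    ``p1_offset`` is the 0-based insert position of the P1 residue; cleavage
    occurs between that residue and the next one.
    """

    peptide: Peptide
    p1_offset: int
    frame_residues: tuple[FrameResidue, ...]

    @property
    def p1_residue(self) -> str:
        return self.peptide.sequence[self.p1_offset]


def enumerate_sites(
    peptide: Peptide,
    p1_set: P1CandidateSet | Iterable[str],
    context: DisplayContext = DisplayContext(),
) -> list[int]:
    """All insert offsets whose residue is an acceptable P1, in ascending order.

    Only insert positions are scanned: cleavage within the arms would not
    release the phage, so arm residues can never be P1.
    """
    residues = set(p1_set.residues if isinstance(p1_set, P1CandidateSet) else p1_set)
    if not residues:
        raise ValueError("P1 candidate set is empty")
    return [i for i, aa in enumerate(peptide.sequence) if aa in residues]


def place_peptide(
    peptide: Peptide,
    offset: int,
    context: DisplayContext = DisplayContext(),
    frame: SubsiteFrame = ALIGNMENT_FRAME,
) -> AlignedPeptide:
    """Anchor *peptide* with P1 at insert position *offset* and fill the frame."""
    if not 0 <= offset < len(peptide.sequence):
        raise ValueError(f"offset {offset} outside insert of length {len(peptide)}")
    seq = context.displayed(peptide.sequence)
    up = len(context.upstream_arm)
    ins = len(peptide.sequence)
    residues = []
    for j, label in enumerate(frame.labels):
        pos = up + offset + (j - frame.p1_index)
        if 0 <= pos < len(seq):
            residues.append(
                FrameResidue(label, seq[pos], arm_derived=not up <= pos < up + ins)
            )
        else:
            residues.append(FrameResidue(label, None))
    return AlignedPeptide(peptide, offset, tuple(residues))


def align_unambiguous(
    peptides: Sequence[Peptide],
    p1_set: P1CandidateSet | Iterable[str],
    context: DisplayContext = DisplayContext(),
    frame: SubsiteFrame = ALIGNMENT_FRAME,
) -> tuple[list[AlignedPeptide], list[Peptide], list[Peptide]]:
    """Partition peptides by anchoring ambiguity.

    Returns ``(aligned, ambiguous, unalignable)``: peptides with exactly one
    candidate P1 are anchored there; those with several go to *ambiguous*;
    those with none to *unalignable*. The partitions are disjoint and cover
    the input.
    """
    aligned, ambiguous, unalignable = [], [], []
    for p in peptides:
        sites = enumerate_sites(p, p1_set, context)
        if len(sites) == 1:
            aligned.append(place_peptide(p, sites[0], context, frame))
        elif sites:
            ambiguous.append(p)
        else:
            unalignable.append(p)
    return aligned, ambiguous, unalignable


@dataclass(frozen=True)
class PositionalProfile:
    """Per-subsite residue counts and probabilities (a probability PWM).

    ``counts`` holds pseudocount-free weighted counts, ``probs`` the
    pseudocount-smoothed probabilities (each row sums to 1), ``effective_n``
    the total weight counted at each subsite (subsites can differ when arm
    positions are masked or fall outside the construct).
    """

    frame: SubsiteFrame
    counts: np.ndarray
    probs: np.ndarray
    effective_n: np.ndarray
    weighting: str = "by_multiplicity"
    arm_policy: str = "mask"
    pseudocount: float = 0.5

    def prob(self, subsite: str, residue: str) -> float:
        return float(self.probs[self.frame.labels.index(subsite), AA_INDEX[residue]])

    def subframe(self, frame: SubsiteFrame) -> "PositionalProfile":
        """Restrict to a narrower frame (e.g. report P4-P4' from a P5-P4' fit)."""
        idx = [self.frame.labels.index(lab) for lab in frame.labels]
        return PositionalProfile(
            frame,
            self.counts[idx],
            self.probs[idx],
            self.effective_n[idx],
            self.weighting,
            self.arm_policy,
            self.pseudocount,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Probabilities as a DataFrame: subsite rows, residue columns."""
        return pd.DataFrame(
            self.probs, index=list(self.frame.labels), columns=list(AMINO_ACIDS)
        )


def _counted(fr: FrameResidue, arm_policy: str) -> bool:
    if fr.residue is None:
        return False
    return arm_policy == "include" or not fr.arm_derived


def build_profile(
    aligned: Sequence[AlignedPeptide],
    pseudocount: float = 0.5,
    weighting: str = "by_multiplicity",
    arm_policy: str = "mask",
) -> PositionalProfile:
    """Count residues per subsite over an alignment and normalize.

    ``weighting="by_multiplicity"`` counts each duplicate clone; ``"unique"``
    counts each distinct sequence once. ``arm_policy="mask"`` (default) skips
    arm-derived residues so the profile reflects only the randomized insert;
    ``"include"`` reproduces figure-style tables where the arms are shown.
    A uniform ``pseudocount`` is added per residue before normalizing.
    """
    if not aligned:
        raise ValueError("cannot build a profile from an empty alignment")
    if weighting not in ("by_multiplicity", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if arm_policy not in ("mask", "include"):
        raise ValueError(f"unknown arm_policy {arm_policy!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    frame = aligned[0].frame_residues
    sframe = SubsiteFrame(
        tuple(fr.subsite for fr in frame),
        [fr.subsite for fr in frame].index("P1"),
    )
    S = len(sframe)
    counts = np.zeros((S, 20))
    for ap in aligned:
        w = ap.peptide.multiplicity if weighting == "by_multiplicity" else 1.0
        for j, fr in enumerate(ap.frame_residues):
            if _counted(fr, arm_policy):
                counts[j, AA_INDEX[fr.residue]] += w
    effective_n = counts.sum(axis=1)
    denom = effective_n + 20 * pseudocount
    probs = np.empty_like(counts)
    for j in range(S):
        if denom[j] > 0:
            probs[j] = (counts[j] + pseudocount) / denom[j]
        else:
            probs[j] = 1.0 / 20  # nothing observed, no pseudocount: uniform
    return PositionalProfile(
        sframe, counts, probs, effective_n, weighting, arm_policy, pseudocount
    )


def empirical_background(peptides: Sequence[Peptide]) -> np.ndarray:
    """Residue composition of a peptide set (multiplicity-weighted), as a 20-vector."""
    counts = np.zeros(20)
    for p in peptides:
        for aa in p.sequence:
            counts[AA_INDEX[aa]] += p.multiplicity
    if counts.sum() == 0:
        raise ValueError("empty peptide set")
    return counts / counts.sum()


def score_offset(
    peptide: Peptide,
    offset: int,
    profile: PositionalProfile,
    background: np.ndarray,
    context: DisplayContext = DisplayContext(),
) -> float:
    """Log-odds fit of anchoring *peptide* at *offset* against the profile.

    Sums ``log(p_subsite(residue) / background(residue))`` over the non-P1
    subsites counted under the profile's arm policy (P1 is excluded because
    it is constrained to the candidate set, not learned). Higher is better.
    """
    background = np.asarray(background, dtype=float)
    ap = place_peptide(peptide, offset, context, profile.frame)
    score = 0.0
    for j, fr in enumerate(ap.frame_residues):
        if fr.subsite == "P1" or not _counted(fr, profile.arm_policy):
            continue
        p = profile.probs[j, AA_INDEX[fr.residue]]
        if p == 0:
            raise ValueError(
                f"zero profile probability for {fr.residue} at {fr.subsite}; "
                "use a pseudocount > 0"
            )
        score += float(np.log(p / background[AA_INDEX[fr.residue]]))
    return score


def _peptide_loglik(
    ap: AlignedPeptide, profile: PositionalProfile, background: np.ndarray
) -> float:
    """Per-clone log-likelihood of an anchored peptide under a profile.

    Subsites counted under the arm policy are scored with the profile (P1
    included: the profile also models which candidate residue is preferred
    at P1). Subsites excluded from the profile - masked arm residues and
    positions outside the construct - are scored with the *background*
    distribution, so placements with different arm overlap remain directly
    comparable; dropping them instead would systematically favour edge
    placements, which see fewer (necessarily negative) log terms.
    """
    ll = 0.0
    for j, fr in enumerate(ap.frame_residues):
        if _counted(fr, profile.arm_policy):
            ll += float(np.log(profile.probs[j, AA_INDEX[fr.residue]]))
        elif fr.residue is not None:
            ll += float(np.log(background[AA_INDEX[fr.residue]]))
        else:
            ll += float(np.log(background.mean()))
    return ll


def _as_background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or (background <= 0).any():
        raise ValueError("background must be a strictly positive 20-vector")
    return background / background.sum()


def total_log_likelihood(
    aligned: Sequence[AlignedPeptide],
    pseudocount: float = 0.5,
    weighting: str = "by_multiplicity",
    arm_policy: str = "mask",
    background: np.ndarray | None = None,
) -> float:
    """Joint log-likelihood of an alignment under its own (smoothed) profile.

    This is the objective the iterative placement maximizes: build the
    profile implied by the assignment, then sum each clone's log-likelihood
    (multiplicity-weighted under ``by_multiplicity``), scoring profile-
    excluded frame positions with *background* (uniform by default).
    """
    bg = _as_background(background)
    profile = build_profile(aligned, pseudocount, weighting, arm_policy)
    total = 0.0
    for ap in aligned:
        w = ap.peptide.multiplicity if weighting == "by_multiplicity" else 1.0
        total += w * _peptide_loglik(ap, profile, bg)
    return total


@dataclass(frozen=True)
class IterativeAlignmentResult:
    """Converged anchoring of all peptides plus the final profile.

    ``ll_trace`` records the joint log-likelihood after each improvement pass
    (non-decreasing by construction); ``converged`` is False only when
    ``max_iter`` passes were exhausted before the assignment stabilized.
    """

    aligned: list[AlignedPeptide]
    profile: PositionalProfile
    n_iterations: int
    converged: bool
    ll_trace: list[float]


def resolve_and_iterate(
    unambiguous: Sequence[AlignedPeptide],
    ambiguous: Sequence[Peptide],
    p1_set: P1CandidateSet | Iterable[str],
    *,
    context: DisplayContext = DisplayContext(),
    frame: SubsiteFrame = ALIGNMENT_FRAME,
    pseudocount: float = 0.5,
    weighting: str = "by_multiplicity",
    arm_policy: str = "mask",
    background: np.ndarray | None = None,
    max_iter: int = 50,
    n_restarts: int = 8,
    tie_rule: str = "nterminal",
    seed_profile: PositionalProfile | None = None,
) -> IterativeAlignmentResult:
    """Anchor ambiguous peptides by iteratively fitting the emerging profile.

    Single-site peptides (``unambiguous``) are fixed anchors. Each ambiguous
    peptide is first placed at the offset maximizing its log-likelihood under
    the profile of the anchors alone (or ``seed_profile``); then single-
    peptide moves that strictly increase the joint log-likelihood
    (:func:`total_log_likelihood`) are applied until no move helps, i.e. the
    assignment is a coordinate-wise maximum of the joint likelihood. Because
    such coordinate ascent can stall in a local maximum, the search is
    repeated from ``n_restarts - 1`` additional deterministic (hash-seeded)
    initial placements and the highest-likelihood converged assignment wins.

    Determinism and input-order invariance: candidate offsets are scored
    exhaustively; exact ties follow ``tie_rule`` (default: the smaller,
    more N-terminal offset); the
    improvement sweep visits peptides in a canonical sequence order, not
    input order; restart initializations depend only on each peptide's
    sequence, so they too are order-invariant.
    """
    if tie_rule not in ("nterminal", "cterminal"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    tie_sign = 1 if tie_rule == "nterminal" else -1
    bg = _as_background(background)
    unambiguous = list(unambiguous)
    ambiguous = list(ambiguous)
    if not unambiguous and seed_profile is None:
        raise ValueError(
            "need at least one unambiguously anchored peptide or a seed profile"
        )
    amb_sites = [enumerate_sites(p, p1_set, context) for p in ambiguous]
    for p, sites in zip(ambiguous, amb_sites):
        if not sites:
            raise ValueError(f"{p.sequence}: no candidate P1 residue; not alignable")
    if not ambiguous:
        profile = seed_profile or build_profile(
            unambiguous, pseudocount, weighting, arm_policy
        )
        ll = (
            total_log_likelihood(unambiguous, pseudocount, weighting, arm_policy, bg)
            if unambiguous
            else 0.0
        )
        return IterativeAlignmentResult(list(unambiguous), profile, 1, True, [ll])

    placements_by_offset = [
        {o: place_peptide(p, o, context, frame) for o in sites}
        for p, sites in zip(ambiguous, amb_sites)
    ]

    # canonical visiting order for the improvement sweep (input-order invariant)
    order = sorted(
        range(len(ambiguous)),
        key=lambda i: (ambiguous[i].sequence, ambiguous[i].multiplicity),
    )

    def assignment(chosen: list[int]) -> list[AlignedPeptide]:
        return list(unambiguous) + [
            by_off[o] for by_off, o in zip(placements_by_offset, chosen)
        ]

    def joint_ll(chosen: list[int]) -> float:
        return total_log_likelihood(
            assignment(chosen), pseudocount, weighting, arm_policy, bg
        )

    movable = [i for i in order if len(amb_sites[i]) > 1]

    # Precompute, per ambiguous peptide and offset, the profile cells it
    # occupies (subsite, residue) and its weighted background contribution,
    # so that candidate moves are evaluated incrementally in O(frame) time.
    S = len(frame)
    logbg = np.log(bg)
    logbg_mean = float(np.log(bg.mean()))
    amb_w = [
        float(p.multiplicity) if weighting == "by_multiplicity" else 1.0
        for p in ambiguous
    ]

    def _cells_and_bg(ap: AlignedPeptide, w: float) -> tuple[list[tuple[int, int]], float]:
        cells, bgc = [], 0.0
        for j, fr in enumerate(ap.frame_residues):
            if _counted(fr, arm_policy):
                cells.append((j, AA_INDEX[fr.residue]))
            elif fr.residue is not None:
                bgc += w * float(logbg[AA_INDEX[fr.residue]])
            else:
                bgc += w * logbg_mean
        return cells, bgc

    amb_cells: list[dict[int, list[tuple[int, int]]]] = []
    amb_bgc: list[dict[int, float]] = []
    for i, by_off in enumerate(placements_by_offset):
        cells_by_o, bgc_by_o = {}, {}
        for o, ap in by_off.items():
            cells_by_o[o], bgc_by_o[o] = _cells_and_bg(ap, amb_w[i])
        amb_cells.append(cells_by_o)
        amb_bgc.append(bgc_by_o)

    base_counts = np.zeros((S, 20))
    const_bg = 0.0
    for ap in unambiguous:
        w = float(ap.peptide.multiplicity) if weighting == "by_multiplicity" else 1.0
        cells, bgc = _cells_and_bg(ap, w)
        for s, a in cells:
            base_counts[s, a] += w
        const_bg += bgc

    pc = pseudocount

    class _State:
        """counts + the profile part of the joint log-likelihood.

        F = sum_s [ sum_a n_sa*log(n_sa + pc) - N_s*log(N_s + 20*pc) ], the
        exact data log-likelihood under the pseudocount-smoothed profile;
        single-cell updates adjust F in O(1).
        """

        def __init__(self) -> None:
            self.counts = base_counts.copy()
            self.N = self.counts.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                g = np.where(
                    self.counts > 0, self.counts * np.log(self.counts + pc), 0.0
                )
                h = np.where(self.N > 0, self.N * np.log(self.N + 20 * pc), 0.0)
            self.F = float(g.sum() - h.sum())

        def _bump(self, s: int, a: int, w: float) -> None:
            n, N = self.counts[s, a], self.N[s]
            n2, N2 = n + w, N + w
            self.F += (n2 * np.log(n2 + pc) if n2 > 0 else 0.0) - (
                n * np.log(n + pc) if n > 0 else 0.0
            )
            self.F -= (N2 * np.log(N2 + 20 * pc) if N2 > 0 else 0.0) - (
                N * np.log(N + 20 * pc) if N > 0 else 0.0
            )
            self.counts[s, a] = n2
            self.N[s] = N2

        def apply(self, cells: list[tuple[int, int]], w: float) -> None:
            for s, a in cells:
                self._bump(s, a, w)

    def ascend(
        chosen: list[int], pair_moves: bool
    ) -> tuple[list[int], float, list[float], bool, int]:
        """Coordinate ascent on the joint likelihood.

        Single-peptide moves until none helps; then, when ``pair_moves``,
        joint two-peptide moves (which escape the most common single-move
        traps); back to single moves after any improvement. With pair moves
        a converged assignment is optimal against every 1- and 2-peptide
        re-placement.
        """
        chosen = list(chosen)
        state = _State()
        for i, o in enumerate(chosen):
            state.apply(amb_cells[i][o], amb_w[i])
        bg_total = const_bg + sum(amb_bgc[i][o] for i, o in enumerate(chosen))

        def move(i: int, o_new: int) -> None:
            nonlocal bg_total
            state.apply(amb_cells[i][chosen[i]], -amb_w[i])
            state.apply(amb_cells[i][o_new], amb_w[i])
            bg_total += amb_bgc[i][o_new] - amb_bgc[i][chosen[i]]
            chosen[i] = o_new

        def current_ll() -> float:
            return state.F + bg_total

        ll = current_ll()
        trace = [ll]
        converged = False
        n_iter = 1
        for _ in range(max_iter):
            changed = False
            for i in movable:
                best_o, best_ll = chosen[i], ll
                for o in amb_sites[i]:
                    if o == chosen[i]:
                        continue
                    old = chosen[i]
                    move(i, o)
                    cand = current_ll()
                    move(i, old)
                    # strictly better wins; exact ties follow the tie rule
                    if cand > best_ll + 1e-12 or (
                        abs(cand - best_ll) <= 1e-12 and tie_sign * o < tie_sign * best_o
                    ):
                        best_o, best_ll = o, cand
                if best_o != chosen[i]:
                    move(i, best_o)
                    ll = best_ll
                    changed = True
            if not changed and pair_moves:
                # pair phase: first strictly improving joint move wins
                improved = False
                for a in range(len(movable)):
                    i = movable[a]
                    for b in range(a + 1, len(movable)):
                        j = movable[b]
                        for oi in amb_sites[i]:
                            for oj in amb_sites[j]:
                                if oi == chosen[i] and oj == chosen[j]:
                                    continue
                                old_i, old_j = chosen[i], chosen[j]
                                move(i, oi)
                                move(j, oj)
                                cand = current_ll()
                                if cand > ll + 1e-12:
                                    ll = cand
                                    improved = True
                                else:
                                    move(i, old_i)
                                    move(j, old_j)
                                if improved:
                                    break
                            if improved:
                                break
                        if improved:
                            break
                    if improved:
                        break
                changed = improved
            n_iter += 1
            trace.append(ll)
            if not changed:
                converged = True
                break
        # one exact evaluation guards against accumulated float drift
        ll = joint_ll(chosen)
        trace[-1] = ll
        return chosen, ll, trace, converged, n_iter

    # start 0: best per-clone fit against the anchor profile alone
    profile0 = seed_profile or build_profile(
        unambiguous, pseudocount, weighting, arm_policy
    )
    starts = [
        [
            max(
                sites,
                key=lambda o: (_peptide_loglik(by_off[o], profile0, bg), -tie_sign * o),
            )
            for sites, by_off in zip(amb_sites, placements_by_offset)
        ]
    ]
    # perturbed restarts: offsets chosen by a stable per-sequence hash
    for r in range(1, max(n_restarts, 1)):
        starts.append(
            [
                sites[
                    zlib.crc32(f"{p.sequence}:{p.multiplicity}:{r}".encode())
                    % len(sites)
                ]
                for p, sites in zip(ambiguous, amb_sites)
            ]
        )

    # For small ambiguous sets every restart is polished with pair moves
    # (restart basins genuinely differ there and exhaustive-level accuracy is
    # wanted); for large sets the anchor profile makes restarts converge to
    # one basin, so the quadratic pair phase runs on the winner only.
    pair_all = len(movable) <= 30
    best = None
    for start in starts:
        chosen, ll, _, _, _ = ascend(start, pair_moves=pair_all)
        key = (ll, tuple(-tie_sign * chosen[i] for i in order))
        if best is None or key > best[0]:
            best = (key, chosen)
    chosen, ll, trace, converged, n_iter = ascend(best[1], pair_moves=True)
    if not converged:
        warnings.warn(
            f"alignment did not stabilize within {max_iter} passes; "
            "returning the last assignment"
        )
    final = assignment(chosen)
    return IterativeAlignmentResult(
        final,
        build_profile(final, pseudocount, weighting, arm_policy),
        n_iter,
        converged,
        trace,
    )
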