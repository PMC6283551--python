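"""Schechter-Berger subsite frames.

Substrate residues are labelled outward from the scissile bond: P1 is the
residue immediately N-terminal of the cut, P1' immediately C-terminal, so a
P5-P4' frame spans nine residues with cleavage between P1 and P1'.
"""

from __future__ import annotations

from dataclasses import dataclass


def _labels(n_p: int, n_prime: int) -> tuple[str, ...]:
    p_side = [f"P{i}" for i in range(n_p, 0, -1)]
    prime_side = [f"P{i}'" for i in range(1, n_prime + 1)]
    return tuple(p_side + prime_side)


@dataclass(frozen=True)
class SubsiteFrame:
    """An ordered window of subsites around the scissile bond.

    ``p1_index`` is the position of P1 within ``labels``; cleavage occurs
    between ``labels[p1_index]`` and ``labels[p1_index + 1]``.
    """

    labels: tuple[str, ...]
    p1_index: int

    def __post_init__(self) -> None:
        if self.labels[self.p1_index] != "P1":
            raise ValueError("p1_index must point at the P1 subsite")
        if self.p1_index + 1 >= len(self.labels) or self.labels[self.p1_index + 1] != "P1'":
            raise ValueError("cleavage must lie between P1 and P1'")

    def __len__(self) -> int:
        return len(self.labels)

    def offset_of(self, label: str) -> int:
        """Signed residue offset of a subsite relative to P1 (P1 -> 0, P1' -> +1)."""
        return self.labels.index(label) - self.p1_index


def make_frame(n_p: int = 5, n_prime: int = 4) -> SubsiteFrame:
    """Build a P{n_p}-P{n_prime}' frame (defaults to the P5-P4' alignment frame)."""
    if n_p < 1 or n_prime < 1:
        raise ValueError("a frame needs at least P1 and P1'")
    return SubsiteFrame(_labels(n_p, n_prime), n_p - 1)


#: Frame used to anchor peptides during alignment.
ALIGNMENT_FRAME = make_frame(5, 4)

#: Frame used for reported percentage tables and logos.
REPORT_FRAME = make_frame(4, 4)
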