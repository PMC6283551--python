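"""Core sequence types: the 20-residue alphabet, display context and peptides.

A substrate phage clone displays a randomized nonamer insert inside a fixed
protein context on the T7 capsid: a short upstream linker ending in ``PGG``
and a downstream hexahistidine tag used to tether the phage to Ni-NTA beads.
Cleavage anywhere inside the insert releases the phage; the flanking arms can
occupy outer subsites of the cleavage frame but are never themselves cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical one-letter alphabet of the 20 standard amino acids.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_ENCODE_TABLE = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _ENCODE_TABLE[ord(_aa)] = _i


def validate_sequence(sequence: str, *, what: str = "sequence") -> None:
    """Raise ``ValueError`` if *sequence* uses letters outside the 20-residue alphabet."""
    bad = sorted(set(sequence) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(
            f"{what} {sequence!r} contains non-standard residue(s): {', '.join(bad)}"
        )


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string as an int8 index array (A=0 .. Y=19)."""
    codes = _ENCODE_TABLE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        validate_sequence(sequence)
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(AMINO_ACIDS[int(c)] for c in codes)


@dataclass(frozen=True)
class DisplayContext:
    """Fixed protein context flanking the randomized insert on the phage capsid.

    Defaults reproduce the ``PGG(X)9HHHHHH`` T7 display construct: a linker
    ending in Pro-Gly-Gly upstream and a His6 purification tag downstream of a
    nine-residue random insert.
    """

    upstream_arm: str = "PGG"
    downstream_arm: str = "HHHHHH"
    insert_length: int = 9

    def __post_init__(self) -> None:
        validate_sequence(self.upstream_arm, what="upstream_arm")
        validate_sequence(self.downstream_arm, what="downstream_arm")
        if self.insert_length < 1:
            raise ValueError(f"insert_length must be >= 1, got {self.insert_length}")

    def displayed(self, insert: str) -> str:
        """Full displayed protein segment for a given insert."""
        return self.upstream_arm + insert + self.downstream_arm


@dataclass(frozen=True, order=True)
class Peptide:
    """A sequenced phage insert with its observed multiplicity.

    Identical inserts recovered from several clones are collapsed into one
    record whose ``multiplicity`` counts the clones, mirroring how duplicate
    sequences are reported next to phage-display alignments.
    """

    sequence: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")

    def __len__(self) -> int:
        return len(self.sequence)


def merge_peptides(peptides: list[Peptide]) -> list[Peptide]:
    """Collapse identical sequences, summing multiplicities.

    Output is sorted by descending multiplicity then sequence, which keeps
    every downstream artifact deterministic regardless of input order.
    """
    totals: dict[str, int] = {}
    for p in peptides:
        totals[p.sequence] = totals.get(p.sequence, 0) + p.multiplicity
    return [
        Peptide(seq, n)
        for seq, n in sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def total_multiplicity(peptides: list[Peptide]) -> int:
    return sum(p.multiplicity for p in peptides)


def encode_peptides(peptides: list[Peptide]) -> tuple[np.ndarray, np.ndarray]:
    """Encode a peptide list into a codes matrix and a count vector."""
    if not peptides:
        raise ValueError("empty peptide list")
    codes = np.stack([encode(p.sequence) for p in peptides])
    counts = np.array([p.multiplicity for p in peptides], dtype=float)
    return codes, counts
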