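"""Readers and writers for every pipeline artifact.

Plain-text formats only: FASTA and CSV for peptide lists (multiplicity in the
FASTA header as ``count=N`` or in a ``count`` column), CSV for kinetic time
courses, TSV for tables (alignments, profiles, grouped percentages, logo
matrices, panel results, rankings, comparisons). Prime subsites are written
with an ASCII apostrophe (``P2'``). Every writer has a matching reader so
artifacts round-trip exactly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignedPeptide, PositionalProfile, place_peptide
from .frames import SubsiteFrame
from .kinetics import EfficiencyRanking, PanelResult, TimeCourse
from .peptides import AMINO_ACIDS, DisplayContext, Peptide

__all__ = [
    "read_peptides",
    "write_peptides_fasta",
    "write_peptides_csv",
    "read_timecourses_csv",
    "write_timecourses_csv",
    "write_panel_tsv",
    "write_ranking_tsv",
    "write_aligned_tsv",
    "read_aligned_tsv",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_grouped_tsv",
    "write_logo_tsv",
    "write_comparison_tsv",
]

_COUNT_RE = re.compile(r"count=(\d+)")


def _validated_peptide(sequence: str, count: int, record: str) -> Peptide:
    bad = sorted(set(sequence) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(
            f"record {record!r}: non-standard residue(s) {', '.join(bad)} "
            f"in sequence {sequence!r}"
        )
    return Peptide(sequence, count)


def read_peptides(path: str | Path, fmt: str | None = None) -> list[Peptide]:
    """Read a peptide list from FASTA or CSV.

    Format is inferred from the extension unless *fmt* is given. FASTA
    multiplicities are parsed from a ``count=N`` token in the description;
    CSV expects ``sequence,count`` columns (a header row is optional and a
    missing count defaults to 1).
    """
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".faa") else "csv"
    peptides: list[Peptide] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            m = _COUNT_RE.search(rec.description)
            count = int(m.group(1)) if m else 1
            peptides.append(_validated_peptide(str(rec.seq).upper(), count, rec.id))
    elif fmt == "csv":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                fields = line.split(",")
                if i == 0 and fields[0].lower() in ("sequence", "seq"):
                    continue
                seq = fields[0].strip().upper()
                count = int(fields[1]) if len(fields) > 1 and fields[1].strip() else 1
                peptides.append(_validated_peptide(seq, count, f"line {i + 1}"))
    else:
        raise ValueError(f"unknown peptide format {fmt!r}")
    if not peptides:
        raise ValueError(f"{path}: no peptide records found")
    return peptides


def write_peptides_fasta(path: str | Path, peptides: Sequence[Peptide]) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=f"clone_{i + 1:04d}",
                  description=f"count={p.multiplicity}")
        for i, p in enumerate(peptides)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_peptides_csv(path: str | Path, peptides: Sequence[Peptide]) -> None:
    with open(path, "w") as fh:
        fh.write("sequence,count\n")
        for p in peptides:
            fh.write(f"{p.sequence},{p.multiplicity}\n")


def write_timecourses_csv(
    path: str | Path,
    courses: Sequence[TimeCourse],
    p1_residues: dict[str, str] | None = None,
) -> None:
    """Write time courses as long-format CSV.

    Columns: substrate_id, [p1_residue,] time_min, value, value_kind.
    """
    rows = []
    for tc in courses:
        for t, v in zip(tc.times, tc.values):
            row = {"substrate_id": tc.substrate_id}
            if p1_residues is not None:
                row["p1_residue"] = p1_residues[tc.substrate_id]
            row.update(time_min=t, value=repr(float(v)), value_kind=tc.value_kind)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timecourses_csv(
    path: str | Path,
) -> tuple[list[TimeCourse], dict[str, str] | None]:
    """Read long-format time-course CSV; returns courses and the P1 map if present."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"substrate_id", "time_min", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    p1_map: dict[str, str] | None = None
    if "p1_residue" in df.columns:
        p1_map = dict(
            df.drop_duplicates("substrate_id")[["substrate_id", "p1_residue"]].values
        )
    courses = []
    for sid, grp in df.groupby("substrate_id", sort=False):
        grp = grp.sort_values("time_min")
        kind = (
            str(grp["value_kind"].iloc[0])
            if "value_kind" in grp.columns
            else "absorbance"
        )
        courses.append(
            TimeCourse(str(sid), grp["time_min"].to_numpy(),
                       grp["value"].to_numpy(), kind)
        )
    return courses, p1_map


def write_panel_tsv(path: str | Path, panel: PanelResult) -> None:
    panel.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_ranking_tsv(path: str | Path, ranking: EfficiencyRanking) -> None:
    ranking.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_aligned_tsv(path: str | Path, aligned: Sequence[AlignedPeptide]) -> None:
    """Write an aligned-peptide table in the figure layout.

    One column per subsite (arm-derived residues lowercase, positions outside
    the construct as ``-``), plus the raw sequence, P1 offset and clone count
    so the alignment can be reconstructed exactly.
    """
    if not aligned:
        raise ValueError("empty alignment")
    labels = [fr.subsite for fr in aligned[0].frame_residues]
    with open(path, "w") as fh:
        fh.write("\t".join(labels + ["sequence", "p1_offset", "count"]) + "\n")
        for ap in aligned:
            cells = [
                "-" if fr.residue is None
                else (fr.residue.lower() if fr.arm_derived else fr.residue)
                for fr in ap.frame_residues
            ]
            fh.write(
                "\t".join(
                    cells
                    + [ap.peptide.sequence, str(ap.p1_offset), str(ap.peptide.multiplicity)]
                )
                + "\n"
            )


def read_aligned_tsv(
    path: str | Path, context: DisplayContext = DisplayContext()
) -> list[AlignedPeptide]:
    df = pd.read_csv(path, sep="\t")
    labels = [c for c in df.columns if c not in ("sequence", "p1_offset", "count")]
    frame = SubsiteFrame(tuple(labels), labels.index("P1"))
    return [
        place_peptide(
            Peptide(row["sequence"], int(row["count"])),
            int(row["p1_offset"]),
            context,
            frame,
        )
        for _, row in df.iterrows()
    ]


def write_profile_tsv(path: str | Path, profile: PositionalProfile) -> None:
    """Write a profile matrix: subsite rows, 20 residue columns, effective_n.

    Probabilities are written at full precision so write-then-read is exact.
    """
    with open(path, "w") as fh:
        fh.write("subsite\t" + "\t".join(AMINO_ACIDS) + "\teffective_n\n")
        for j, lab in enumerate(profile.frame.labels):
            vals = "\t".join(repr(float(x)) for x in profile.probs[j])
            fh.write(f"{lab}\t{vals}\t{repr(float(profile.effective_n[j]))}\n")


def read_profile_tsv(path: str | Path) -> PositionalProfile:
    """Read a profile matrix written by :func:`write_profile_tsv`.

    Raw counts are not stored in the artifact; they are reconstructed as
    ``probs * effective_n`` scaled to the stored effective_n (exact when the
    profile was written with pseudocount 0, approximate otherwise).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = tuple(df.index)
    frame = SubsiteFrame(labels, labels.index("P1"))
    probs = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    effective_n = df["effective_n"].to_numpy(dtype=float)
    counts = probs * effective_n[:, None]
    return PositionalProfile(frame, counts, probs, effective_n)


def write_grouped_tsv(path: str | Path, grouped: pd.DataFrame) -> None:
    grouped.to_csv(path, sep="\t", index_label="subsite",
                   float_format="%.10g")


def write_logo_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="subsite",
                  float_format="%.10g")


def write_comparison_tsv(path: str | Path, divergence: pd.Series) -> None:
    divergence.rename_axis("subsite").to_frame().to_csv(
        path, sep="\t", float_format="%.10g"
    )
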