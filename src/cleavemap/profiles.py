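"""Reporting layer: class-grouped percentages, probability logos, comparisons.

Two residue groupings are used side by side, as is common in phage-display
specificity reports: a six-class chemical grouping for percentage tables
(aromatic / acidic / basic / small aliphatic / large aliphatic / hydrophilic)
and a five-class colour scheme for probability logos (where His is coloured
with the basic residues even though the grouping counts it as hydrophilic).
Both are exposed as named :class:`ClassScheme` objects rather than silently
merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import PositionalProfile
from .peptides import AA_INDEX, AMINO_ACIDS

__all__ = [
    "ClassScheme",
    "GROUPING_SCHEME",
    "LOGO_COLOR_SCHEME",
    "LOGO_COLORS",
    "LogoMatrix",
    "group_percentages",
    "logo_matrix",
    "consensus_string",
    "p2prime_acidity",
    "profile_divergence",
    "render_logo",
]


@dataclass(frozen=True)
class ClassScheme:
    """Named partition of the 20 residues into disjoint covering groups."""

    name: str
    classes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.classes.items():
            overlap = seen & members
            if overlap:
                raise ValueError(
                    f"scheme {self.name!r}: residues in several classes: {sorted(overlap)}"
                )
            seen |= members
        missing = sorted(set(AMINO_ACIDS) - seen)
        if missing:
            raise ValueError(
                f"scheme {self.name!r} does not cover residues: {', '.join(missing)}"
            )
        extra = sorted(seen - set(AMINO_ACIDS))
        if extra:
            raise ValueError(f"scheme {self.name!r}: non-standard residues {extra}")

    def class_of(self, residue: str) -> str:
        for label, members in self.classes.items():
            if residue in members:
                return label
        raise KeyError(residue)


#: Chemical grouping used for percentage tables.
GROUPING_SCHEME = ClassScheme(
    "grouping",
    {
        "aromatic": frozenset("FYW"),
        "acidic": frozenset("DE"),
        "basic": frozenset("KR"),
        "small_aliphatic": frozenset("GA"),
        "large_aliphatic": frozenset("VLIP"),
        "hydrophilic": frozenset("STHNQCM"),
    },
)

#: Colour classes used for probability logos (note His sits with K/R here).
LOGO_COLOR_SCHEME = ClassScheme(
    "logo_colors",
    {
        "yellow": frozenset("KRH"),
        "red": frozenset("DE"),
        "green": frozenset("FYW"),
        "white": frozenset("STCMNQ"),
        "blue": frozenset("GAVLIP"),
    },
)

#: Residue -> colour name, derived from :data:`LOGO_COLOR_SCHEME`.
LOGO_COLORS: dict[str, str] = {
    aa: color for color, members in LOGO_COLOR_SCHEME.classes.items() for aa in members
}


def group_percentages(
    profile: PositionalProfile, scheme: ClassScheme = GROUPING_SCHEME
) -> pd.DataFrame:
    """Per-subsite class percentages (rows: subsites, columns: classes).

    Each class percentage is the sum of its member residues' percentages, so
    rows sum to 100 exactly (up to float rounding).
    """
    rows = {}
    for j, subsite in enumerate(profile.frame.labels):
        rows[subsite] = {
            label: 100.0 * sum(profile.probs[j, AA_INDEX[aa]] for aa in members)
            for label, members in scheme.classes.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(scheme.classes))


@dataclass(frozen=True)
class LogoMatrix:
    """Probability-unit logo data: subsite x residue matrix plus colours."""

    matrix: pd.DataFrame
    color_map: dict[str, str]
    y_axis: str = "probability"

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("logo columns must each sum to 1")
        missing = sorted(set(AMINO_ACIDS) - set(self.color_map))
        if missing:
            raise ValueError(f"color_map misses residues: {missing}")


def logo_matrix(profile: PositionalProfile) -> LogoMatrix:
    """Package a profile as a probability logo matrix with standard colours."""
    return LogoMatrix(profile.to_dataframe(), dict(LOGO_COLORS))


def consensus_string(
    profile: PositionalProfile,
    major_threshold: float = 0.5,
    scheme: ClassScheme = GROUPING_SCHEME,
) -> str:
    """Compact one-symbol-per-subsite summary of a profile.

    A subsite shows its top residue (uppercase) if that residue reaches
    ``major_threshold``; otherwise the initial of the top residue class in
    lowercase if that class reaches the threshold; otherwise ``x``.
    """
    if not 0 < major_threshold <= 1:
        raise ValueError("major_threshold must lie in (0, 1]")
    out = []
    pct = group_percentages(profile, scheme) / 100.0
    for j, subsite in enumerate(profile.frame.labels):
        top = int(np.argmax(profile.probs[j]))
        if profile.probs[j, top] >= major_threshold:
            out.append(AMINO_ACIDS[top])
            continue
        cls = pct.loc[subsite]
        if cls.max() >= major_threshold:
            out.append(str(cls.idxmax())[0].lower())
        else:
            out.append("x")
    return "".join(out)


def p2prime_acidity(profile: PositionalProfile) -> float:
    """Probability mass of Asp + Glu at the P2' subsite."""
    if "P2'" not in profile.frame.labels:
        raise ValueError("profile frame has no P2' subsite")
    j = profile.frame.labels.index("P2'")
    return float(profile.probs[j, AA_INDEX["D"]] + profile.probs[j, AA_INDEX["E"]])


def _jsd_base2(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def profile_divergence(a: PositionalProfile, b: PositionalProfile) -> pd.Series:
    """Per-subsite Jensen-Shannon divergence (base 2, in [0, 1]) between profiles."""
    if a.frame.labels != b.frame.labels:
        raise ValueError(
            f"frame mismatch: {a.frame.labels} vs {b.frame.labels}"
        )
    vals = [
        _jsd_base2(a.probs[j], b.probs[j]) for j in range(len(a.frame.labels))
    ]
    return pd.Series(vals, index=list(a.frame.labels), name="jsd")


def render_logo(logo: LogoMatrix, path: str, *, title: str = "") -> None:
    """Render a simple stacked-letter probability logo to an image file.

    Letters at each subsite are stacked by probability (largest on top),
    scaled to their probability and coloured by the logo colour classes.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    named = {"white": "#d9d9d9"}  # plain white is invisible on white canvases
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    fig, ax = plt.subplots(figsize=(0.8 * len(logo.matrix) + 1, 3))
    for x, (subsite, row) in enumerate(logo.matrix.iterrows()):
        y = 0.0
        for aa, p in sorted(row.items(), key=lambda kv: kv[1]):
            if p < 0.01:
                continue
            tp = TextPath((0, 0), aa, size=1.0, prop=fp)
            bb = tp.get_extents()
            tr = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, p / bb.height)
                .translate(x + 0.05, y)
            )
            color = logo.color_map[aa]
            ax.add_patch(
                PathPatch(tr.transform_path(tp), facecolor=named.get(color, color),
                          edgecolor="black", linewidth=0.2)
            )
            y += p
    ax.set_xlim(0, len(logo.matrix))
    ax.set_ylim(0, 1)
    ax.set_xticks(np.arange(len(logo.matrix)) + 0.5)
    ax.set_xticklabels(list(logo.matrix.index))
    ax.set_ylabel(logo.y_axis)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
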