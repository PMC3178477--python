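"""Three-dimensional G-statistic specificity screening.

With three cancer groups there are three pairwise comparisons; each protein
maps to a point (x, y, z) of its three (unsigned, Yates-corrected) G values.
Following the screen's convention the axes are

    x: group1 vs group3, y: group3 vs group2, z: group1 vs group2

so for groups (LCNEC, SCLC, LCC): x = LCNEC vs LCC, y = LCC vs SCLC,
z = LCNEC vs SCLC. A protein expressed specifically in one group lies on or
near the coordinate plane spanned by the two comparisons involving that
group: e.g. a group-1-specific protein sits in the region x > 3.84 and
z > 3.84 (each corresponding to p < 0.05 for one degree of freedom) with a
small y. Because G is unsigned, the direction of enrichment is read from the
pooled counts; both significant comparisons must favour the focal group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairwise import PairwiseResult, g_statistic
from .pooling import GroupPooledCounts

__all__ = [
    "G_CRIT_05",
    "TripleCoordinates",
    "CategorySummary",
    "triple_coordinates",
    "classify_specific",
    "extract_candidates",
    "summarize_categories",
    "coordinates_to_frame",
    "plot_coordinates",
]

# chi-square(1 df) critical value at p = 0.05
G_CRIT_05 = 3.84

NONSIGNIFICANT = "nonsignificant"
MIXED = "mixed"


@dataclass
class TripleCoordinates:
    """One protein's three pairwise G values and its specificity label.

    ``directions`` maps each ordered pair to the group label with the higher
    pooled count (``None`` for a tie or a double-zero pair).
    """

    protein_id: str
    gx: float
    gy: float
    gz: float
    pairs: tuple[tuple[str, str], tuple[str, str], tuple[str, str]]
    directions: dict[tuple[str, str], str | None] = field(default_factory=dict)
    label: str = NONSIGNIFICANT

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.gx, self.gy, self.gz)


def _default_pairs(groups: list[str]) -> tuple:
    g1, g2, g3 = groups
    return ((g1, g3), (g3, g2), (g1, g2))


def triple_coordinates(
    pooled: GroupPooledCounts,
    ordered_pairs: tuple | None = None,
    g_crit: float = G_CRIT_05,
) -> list[TripleCoordinates]:
    """Map every protein to its (x, y, z) pairwise G point and classify it.

    ``ordered_pairs`` fixes the axis convention; the default for groups
    (A, B, C) is x=(A,C), y=(C,B), z=(A,B). A pair in which the protein was
    counted in neither group contributes coordinate exactly 0.
    """
    if len(pooled.groups) != 3:
        raise ValueError(f"need exactly 3 groups, have {pooled.groups}")
    pairs = tuple(ordered_pairs) if ordered_pairs else _default_pairs(pooled.groups)
    if len(pairs) != 3:
        raise ValueError("need exactly 3 ordered pairs")
    gvals = []
    dirs = []
    for a, b in pairs:
        n_a = pooled.counts_for(a)
        n_b = pooled.counts_for(b)
        gvals.append(
            g_statistic(n_a, pooled.total_for(a), n_b, pooled.total_for(b), yates=True)
        )
        dirs.append(np.where(n_a > n_b, 1, np.where(n_b > n_a, -1, 0)))
    out = []
    for i, pid in enumerate(pooled.protein_ids):
        directions = {}
        for (a, b), d in zip(pairs, dirs):
            directions[(a, b)] = a if d[i] > 0 else (b if d[i] < 0 else None)
        tc = TripleCoordinates(
            protein_id=pid,
            gx=float(gvals[0][i]),
            gy=float(gvals[1][i]),
            gz=float(gvals[2][i]),
            pairs=pairs,
            directions=directions,
        )
        tc.label = classify_specific(tc, g_crit=g_crit)
        out.append(tc)
    return out


def classify_specific(coords: TripleCoordinates, g_crit: float = G_CRIT_05) -> str:
    """Label a protein by the plane rule.

    ``"<group>-specific"`` when both comparisons involving the group exceed
    ``g_crit``, both favour that group, and the remaining comparison is below
    ``g_crit`` (the point lies near or on that coordinate plane);
    ``"nonsignificant"`` when no comparison exceeds ``g_crit``; ``"mixed"``
    otherwise.
    """
    pairs = coords.pairs
    gs = {pairs[0]: coords.gx, pairs[1]: coords.gy, pairs[2]: coords.gz}
    groups = sorted({g for p in pairs for g in p})
    for grp in groups:
        involving = [p for p in pairs if grp in p]
        other = [p for p in pairs if grp not in p]
        if len(involving) != 2 or len(other) != 1:
            continue
        if (
            all(gs[p] > g_crit for p in involving)
            and all(coords.directions.get(p) == grp for p in involving)
            and gs[other[0]] < g_crit
        ):
            return f"{grp}-specific"
    if all(v <= g_crit for v in gs.values()):
        return NONSIGNIFICANT
    return MIXED


def extract_candidates(
    coords: list[TripleCoordinates],
    pairwise_results: list[PairwiseResult],
    focal_group: str,
) -> pd.DataFrame:
    """Ranked table of proteins specific to ``focal_group``.

    Ranked by ascending p of the focal pair (the pairwise result supplied),
    ties broken by descending R_SC. ``pairwise_results`` must come from a
    comparison involving the focal group — normally the pair of primary
    interest (e.g. LCNEC vs SCLC).
    """
    groups = {g for c in coords for p in c.pairs for g in p}
    if coords and focal_group not in groups:
        raise ValueError(f"unknown group {focal_group!r}")
    by_id = {r.protein_id: r for r in pairwise_results}
    rows = []
    for c in coords:
        if c.label != f"{focal_group}-specific":
            continue
        r = by_id.get(c.protein_id)
        rows.append(
            {
                "protein_id": c.protein_id,
                "protein_name": r.protein_name if r else c.protein_id,
                "gx": c.gx,
                "gy": c.gy,
                "gz": c.gz,
                "p": r.p if r else np.nan,
                "r_sc": r.r_sc if r else np.nan,
                "p_fisher": r.p_fisher if r else None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "protein_name", "gx", "gy", "gz", "p", "r_sc", "p_fisher",
        ],
    )
    if len(df):
        df = df.sort_values(["p", "r_sc"], ascending=[True, False]).reset_index(
            drop=True
        )
    return df


@dataclass(frozen=True)
class CategorySummary:
    """Counts and fractions of proteins per functional category."""

    comparison: str
    counts: dict[str, int]
    fractions: dict[str, float]
    n_unannotated: int


def summarize_categories(
    protein_ids: list[str],
    annotation_map: dict[str, "set[str]"],
    comparison: str = "",
) -> CategorySummary:
    """Tally functional categories over a protein list.

    A protein carrying several categories contributes once to each;
    fractions are per-category counts over the number of annotated proteins.
    Annotation acquisition is the caller's concern — any mapping of protein
    id to a set of category labels works.
    """
    counts: Counter = Counter()
    n_unannotated = 0
    n_annotated = 0
    for pid in protein_ids:
        cats = annotation_map.get(pid)
        if not cats:
            n_unannotated += 1
            continue
        n_annotated += 1
        for cat in cats:
            counts[cat] += 1
    fractions = {
        c: k / n_annotated for c, k in counts.items()
    } if n_annotated else {}
    return CategorySummary(
        comparison=comparison,
        counts=dict(counts),
        fractions=fractions,
        n_unannotated=n_unannotated,
    )


def coordinates_to_frame(coords: list[TripleCoordinates]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in coords],
            "gx": [c.gx for c in coords],
            "gy": [c.gy for c in coords],
            "gz": [c.gz for c in coords],
            "label": [c.label for c in coords],
        }
    )


def plot_coordinates(coords: list[TripleCoordinates], path) -> None:
    """Emit the 3-axis scatter to an image file (cosmetic convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    xs = [c.gx for c in coords]
    ys = [c.gy for c in coords]
    zs = [c.gz for c in coords]
    labels = [c.label for c in coords]
    palette = {}
    for lab in sorted(set(labels)):
        palette.setdefault(lab, f"C{len(palette)}")
    ax.scatter(xs, ys, zs, c=[palette[l] for l in labels], s=8)
    ax.set_xlabel("G (pair x)")
    ax.set_ylabel("G (pair y)")
    ax.set_zlabel("G (pair z)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
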