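"""Replicate pooling, R_SC fold changes, identification overlaps, group summaries.

Spectral counts from all runs of a group (triplicate injections of every
patient) are pooled by plain summation — no per-run normalisation — giving a
per-protein group count ``n[p, g]`` and a group total ``t_g = sum_p n[p, g]``.
The pooled counts feed both the fold-change measure and the pairwise G-test.

The fold change between groups A and B is the pseudocount-regularised log2
spectral-count ratio

    R_SC = log2((n_A + f) / (n_B + f)) + log2((t_B - n_B + f) / (t_A - n_A + f))

with ``f = 1.25`` by default. The second term offsets unequal sequencing
depth; R_SC is finite for any nonnegative counts (including zeros) and
exactly antisymmetric under swapping the two groups. R_SC > 1 means more
than a two-fold excess in A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .count_model import CountMatrix

__all__ = [
    "GroupPooledCounts",
    "FoldChange",
    "VennPartition",
    "pool_counts",
    "rsc_value",
    "compute_rsc",
    "venn_partition",
    "group_count_summary",
    "GroupSummary",
]

DEFAULT_PSEUDOCOUNT = 1.25


@dataclass
class GroupPooledCounts:
    """Per-protein pooled counts ``n`` (proteins x groups) and totals ``t``."""

    protein_ids: list[str]
    groups: list[str]
    n: np.ndarray
    t: np.ndarray
    protein_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.int64)
        if self.n.shape != (len(self.protein_ids), len(self.groups)):
            raise ValueError("n shape mismatch")
        if self.t.shape != (len(self.groups),):
            raise ValueError("t shape mismatch")
        if (self.n < 0).any() or (self.t < 0).any():
            raise ValueError("pooled counts must be nonnegative")
        if not np.array_equal(self.n.sum(axis=0), self.t):
            raise ValueError("group totals must equal column sums of n")
        if not self.protein_names:
            self.protein_names = list(self.protein_ids)

    def group_index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise ValueError(f"unknown group {group!r}; have {self.groups}") from None

    def counts_for(self, group: str) -> np.ndarray:
        return self.n[:, self.group_index(group)]

    def total_for(self, group: str) -> int:
        return int(self.t[self.group_index(group)])

    def protein_index(self, protein_id: str) -> int:
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(protein_id) from None


@dataclass(frozen=True)
class FoldChange:
    """Log2 spectral-count ratio of one protein between a group pair."""

    protein_id: str
    group_pair: tuple[str, str]
    r_sc: float
    f: float = DEFAULT_PSEUDOCOUNT


def pool_counts(matrix: CountMatrix, by: str = "group") -> GroupPooledCounts:
    """Sum counts over all runs of each group (or patient).

    ``by="group"`` pools every replicate of every patient in a group;
    ``by="patient"`` pools triplicates within a patient only.
    """
    if by == "group":
        keys = [s.group for s in matrix.samples]
    elif by == "patient":
        keys = [f"{s.group}:{s.patient_id}" for s in matrix.samples]
    else:
        raise ValueError(f"unknown pooling key {by!r}")
    order: list[str] = []
    for k in keys:
        if k not in order:
            order.append(k)
    if not order:
        raise ValueError("matrix has no samples to pool")
    cols = np.array([order.index(k) for k in keys])
    n = np.zeros((matrix.n_proteins, len(order)), dtype=np.int64)
    np.add.at(n.T, cols, matrix.counts.T)
    return GroupPooledCounts(
        protein_ids=list(matrix.protein_ids),
        groups=order,
        n=n,
        t=n.sum(axis=0),
        protein_names=list(matrix.protein_names),
    )


def rsc_value(n_a, n_b, t_a, t_b, f: float = DEFAULT_PSEUDOCOUNT):
    """R_SC for counts ``n_a``/``n_b`` under totals ``t_a``/``t_b`` (vectorised)."""
    if f < 0:
        raise ValueError(f"pseudocount must be nonnegative, got {f}")
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    return np.log2((n_a + f) / (n_b + f)) + np.log2((t_b - n_b + f) / (t_a - n_a + f))


def compute_rsc(
    pooled: GroupPooledCounts,
    pair: tuple[str, str],
    f: float = DEFAULT_PSEUDOCOUNT,
) -> list[FoldChange]:
    """One :class:`FoldChange` per protein for the ordered group ``pair``."""
    a, b = pair
    r = rsc_value(
        pooled.counts_for(a),
        pooled.counts_for(b),
        pooled.total_for(a),
        pooled.total_for(b),
        f=f,
    )
    return [
        FoldChange(protein_id=pid, group_pair=(a, b), r_sc=float(v), f=f)
        for pid, v in zip(pooled.protein_ids, r)
    ]


@dataclass(frozen=True)
class VennPartition:
    """Sizes of the 7 regions of a 3-set identification overlap."""

    unique_a: int
    unique_b: int
    unique_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def total_a(self) -> int:
        return self.unique_a + self.ab_only + self.ac_only + self.abc

    @property
    def total_b(self) -> int:
        return self.unique_b + self.ab_only + self.bc_only + self.abc

    @property
    def total_c(self) -> int:
        return self.unique_c + self.ac_only + self.bc_only + self.abc

    @property
    def union_size(self) -> int:
        return (
            self.unique_a + self.unique_b + self.unique_c
            + self.ab_only + self.ac_only + self.bc_only + self.abc
        )


def venn_partition(ids_a: set, ids_b: set, ids_c: set) -> VennPartition:
    """Partition three identification sets into their 7 exclusive regions."""
    a, b, c = set(ids_a), set(ids_b), set(ids_c)
    abc = a & b & c
    return VennPartition(
        unique_a=len(a - b - c),
        unique_b=len(b - a - c),
        unique_c=len(c - a - b),
        ab_only=len((a & b) - c),
        ac_only=len((a & c) - b),
        bc_only=len((b & c) - a),
        abc=len(abc),
    )


@dataclass(frozen=True)
class GroupSummary:
    """Per-group means/SDs and the one-way ANOVA over the groups."""

    groups: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    f_statistic: float
    p_value: float


def group_count_summary(values_by_group: dict[str, "list[float]"]) -> GroupSummary:
    """Means, SDs (N-1 denominator) and one-way ANOVA across groups.

    Used for per-patient pooled totals and for patient ages: the check that
    neither total sampling depth nor age differs systematically between the
    cancer groups being compared.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    for g, v in values_by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    groups = tuple(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrays)) == 0:
        f_stat, p = 0.0, 1.0  # every value identical: no variance at all
    else:
        f_stat, p = stats.f_oneway(*arrays)
        if np.isnan(f_stat):
            f_stat, p = 0.0, 1.0
    return GroupSummary(
        groups=groups,
        means=tuple(float(a.mean()) for a in arrays),
        sds=tuple(float(a.std(ddof=1)) for a in arrays),
        f_statistic=float(f_stat),
        p_value=float(p),
    )
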