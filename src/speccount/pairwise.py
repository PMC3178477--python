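"""Pairwise G-tests on 2x2 spectral-count contingency tables.

For each protein and each ordered pair of cancer groups (A, B) a 2x2 table is
built with rows "this protein" / "all other proteins" and columns for the two
groups:

    a = n_A          b = t_A - n_A
    c = n_B          d = t_B - n_B

where ``n`` are pooled spectral counts and ``t`` the group totals. The
likelihood-ratio (G) test of independence is

    G = 2 * sum O' ln(O' / E)

with expected counts ``E`` from the (uncorrected) margins and, under the
Yates continuity correction, observed counts ``O'`` shifted 0.5 toward their
expectation (clamped at ``E`` when closer than 0.5). G is referred to the
chi-square distribution with one degree of freedom. The correction makes the
test usable on tables with small counts, including zeros; a protein absent
from both groups is assigned G = 0 (p = 1) by convention.

Because the asymptotic p-values of small-count tables deserve caution, the
module also provides distribution-free verification: the one-sided Fisher
exact (hypergeometric) probability on the same table, and an exact
permutational Mann-Whitney test on per-run counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pooling import DEFAULT_PSEUDOCOUNT, GroupPooledCounts, rsc_value

__all__ = [
    "Contingency2x2",
    "GTestResult",
    "ExactTestResult",
    "PairwiseResult",
    "build_table",
    "g_test",
    "g_statistic",
    "chi2_tail",
    "fisher_exact",
    "mann_whitney_exact",
    "pairwise_differential",
    "results_to_frame",
]


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (a, b) = focal/other in group A; (c, d) = focal/other in group B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def t_a(self) -> int:
        return self.a + self.b

    @property
    def t_b(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class GTestResult:
    g: float
    p_chi2: float
    yates: bool


@dataclass(frozen=True)
class ExactTestResult:
    p_fisher: float
    p_mannwhitney: float | None = None


def build_table(
    pooled: GroupPooledCounts, protein_id: str, pair: tuple[str, str]
) -> Contingency2x2:
    """The 2x2 table for one protein and one ordered group pair."""
    i = pooled.protein_index(protein_id)
    a = int(pooled.counts_for(pair[0])[i])
    c = int(pooled.counts_for(pair[1])[i])
    return Contingency2x2(
        a=a, b=pooled.total_for(pair[0]) - a, c=c, d=pooled.total_for(pair[1]) - c
    )


def g_statistic(a, t_a, c, t_b, yates: bool = True) -> np.ndarray:
    """Vectorised G statistic for tables (a, t_a - a, c, t_b - c).

    ``a``/``c`` may be arrays (one table per element); ``t_a``/``t_b`` are
    scalars or arrays broadcast against them. Tables with both focal counts
    zero return G = 0.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    O = np.stack(np.broadcast_arrays(a, t_a - a, c, t_b - c), axis=-1)
    if (O < 0).any():
        raise ValueError("negative cell in contingency table")
    row_a = O[..., 0] + O[..., 1]
    row_c = O[..., 2] + O[..., 3]
    col1 = O[..., 0] + O[..., 2]
    col2 = O[..., 1] + O[..., 3]
    total = row_a + row_c
    with np.errstate(divide="ignore", invalid="ignore"):
        E = (
            np.stack(
                [row_a * col1, row_a * col2, row_c * col1, row_c * col2], axis=-1
            )
            / total[..., None]
        )
        if yates:
            shift = np.minimum(np.abs(O - E), 0.5)
            Op = O - np.sign(O - E) * shift
        else:
            Op = O
        terms = np.where(Op > 0, Op * np.log(np.where(Op > 0, Op, 1.0) / E), 0.0)
    g = 2.0 * np.nansum(terms, axis=-1)
    # absent from both groups: G = 0 by convention
    g = np.where((O[..., 0] == 0) & (O[..., 2] == 0), 0.0, g)
    return np.maximum(g, 0.0)


def g_test(table: Contingency2x2, yates: bool = True) -> GTestResult:
    """Yates-corrected (default) G-test of one 2x2 table."""
    g = float(g_statistic(table.a, table.t_a, table.c, table.t_b, yates=yates)[0])
    return GTestResult(g=g, p_chi2=chi2_tail(g), yates=yates)


def chi2_tail(g, df: int = 1):
    """Upper-tail chi-square probability of a G (or chi-square) statistic."""
    g_arr = np.asarray(g, dtype=float)
    if (g_arr < 0).any():
        raise ValueError("statistic must be nonnegative")
    p = stats.chi2.sf(g_arr, df)
    return float(p) if np.isscalar(g) or g_arr.ndim == 0 else p


def fisher_exact(table: Contingency2x2, alternative: str = "greater") -> float:
    """Fisher exact probability of the table.

    ``alternative="greater"`` (default) is the one-sided tail toward
    enrichment of the focal protein in group A — the direction in which a
    screened candidate was selected; ``"two-sided"`` sums all tables at most
    as probable as the observed one.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(
        stats.fisher_exact(
            [[table.a, table.b], [table.c, table.d]], alternative=alternative
        ).pvalue
    )


def _rank_sum_two_sided(pooled_values: np.ndarray, n_a: int, w_obs: float) -> float:
    """Exact two-sided permutational p of the mid-rank sum, by enumeration."""
    ranks = stats.rankdata(pooled_values)  # mid-ranks for ties
    total = len(ranks)
    mean_w = n_a * (total + 1) / 2.0
    dev_obs = abs(w_obs - mean_w)
    hits = 0
    n_comb = 0
    for idx in itertools.combinations(range(total), n_a):
        w = ranks[list(idx)].sum()
        if abs(w - mean_w) >= dev_obs - 1e-9:
            hits += 1
        n_comb += 1
    return hits / n_comb


def mann_whitney_exact(counts_a, counts_b) -> float:
    """Exact two-sided Mann-Whitney (rank-sum) test on per-run counts.

    The full permutational distribution of the mid-rank sum is enumerated
    when both sides have at most 10 observations; larger samples fall back
    to the tie-corrected normal approximation, where exactness no longer
    matters.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.size == 0 or counts_b.size == 0:
        raise ValueError("both samples must be non-empty")
    if counts_a.size <= 10 and counts_b.size <= 10:
        pooled = np.concatenate([counts_a, counts_b])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[: counts_a.size].sum()
        return _rank_sum_two_sided(pooled, counts_a.size, w_obs)
    return float(
        stats.mannwhitneyu(
            counts_a, counts_b, alternative="two-sided", method="asymptotic"
        ).pvalue
    )


@dataclass(frozen=True)
class PairwiseResult:
    """Per-protein outcome of the differential screen for one group pair."""

    protein_id: str
    protein_name: str
    group_pair: tuple[str, str]
    n_a: int
    n_b: int
    g: float
    p: float
    r_sc: float
    significant: bool
    candidate: bool
    p_fisher: float | None = None


def pairwise_differential(
    pooled: GroupPooledCounts,
    pair: tuple[str, str],
    alpha: float = 0.05,
    rsc_threshold: float = 1.0,
    f: float = DEFAULT_PSEUDOCOUNT,
    yates: bool = True,
    with_fisher: bool = False,
) -> list[PairwiseResult]:
    """Screen every protein between two groups; sorted by descending R_SC.

    A protein is ``significant`` when its Yates-corrected G-test p-value is
    below ``alpha``, and a ``candidate`` when additionally |R_SC| exceeds
    ``rsc_threshold`` (more than two-fold change at the default threshold 1).
    """
    a, b = pair
    if a not in pooled.groups or b not in pooled.groups:
        raise ValueError(f"unknown pair {pair!r}; groups are {pooled.groups}")
    n_a = pooled.counts_for(a)
    n_b = pooled.counts_for(b)
    t_a = pooled.total_for(a)
    t_b = pooled.total_for(b)
    g = g_statistic(n_a, t_a, n_b, t_b, yates=yates)
    p = stats.chi2.sf(g, 1)
    p = np.where((n_a == 0) & (n_b == 0), 1.0, p)
    r = rsc_value(n_a, n_b, t_a, t_b, f=f)
    results = []
    for i, pid in enumerate(pooled.protein_ids):
        sig = bool(p[i] < alpha)
        pf = None
        if with_fisher:
            alt = "greater" if n_a[i] >= n_b[i] else "less"
            pf = fisher_exact(
                Contingency2x2(
                    int(n_a[i]), t_a - int(n_a[i]), int(n_b[i]), t_b - int(n_b[i])
                ),
                alternative=alt,
            )
        results.append(
            PairwiseResult(
                protein_id=pid,
                protein_name=pooled.protein_names[i],
                group_pair=(a, b),
                n_a=int(n_a[i]),
                n_b=int(n_b[i]),
                g=float(g[i]),
                p=float(p[i]),
                r_sc=float(r[i]),
                significant=sig,
                candidate=sig and abs(r[i]) > rsc_threshold,
                p_fisher=pf,
            )
        )
    results.sort(key=lambda x: -x.r_sc)
    return results


def results_to_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    """Tabulate screen results in the standard output column order."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "protein_name": [r.protein_name for r in results],
            "count_a": [r.n_a for r in results],
            "count_b": [r.n_b for r in results],
            "g": [r.g for r in results],
            "p": [r.p for r in results],
            "r_sc": [r.r_sc for r in results],
            "significant": [r.significant for r in results],
            "candidate": [r.candidate for r in results],
            "p_fisher": [r.p_fisher for r in results],
        }
    )
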