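"""G-test, chi-square tail, exact tests and the pairwise differential screen."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from speccount import (
    Contingency2x2,
    CountMatrix,
    SampleInfo,
    build_table,
    chi2_tail,
    fisher_exact,
    g_statistic,
    g_test,
    mann_whitney_exact,
    pairwise_differential,
    pool_counts,
)


def g_direct(a, b, c, d):
    """Four-term textbook G = 2 sum O ln(O/E), no correction."""
    n = a + b + c + d
    total = 0.0
    for obs, row, col in [
        (a, a + b, a + c), (b, a + b, b + d), (c, c + d, a + c), (d, c + d, b + d),
    ]:
        e = row * col / n
        if obs > 0:
            total += obs * math.log(obs / e)
    return 2 * total


class TestBuildTable:
    def test_cells_from_pooled_counts(self):
        samples = [SampleInfo("a1", "A", "pa", 1), SampleInfo("b1", "B", "pb", 1)]
        m = CountMatrix(
            ["P1", "P2"], samples, np.array([[25, 0], [7639, 10975]])
        )
        t = build_table(pool_counts(m), "P1", ("A", "B"))
        assert (t.a, t.b, t.c, t.d) == (25, 7639, 0, 10975)

    def test_absent_protein_raises_key_error(self):
        samples = [SampleInfo("a1", "A", "pa", 1), SampleInfo("b1", "B", "pb", 1)]
        m = CountMatrix(["P1"], samples, np.array([[1, 1]]))
        with pytest.raises(KeyError):
            build_table(pool_counts(m), "NOPE", ("A", "B"))


class TestGTest:
    def test_proportional_table_gives_zero(self):
        r = g_test(Contingency2x2(10, 90, 20, 180), yates=False)
        assert r.g == pytest.approx(0.0, abs=1e-12)
        assert r.p_chi2 == 1.0

    def test_double_zero_convention(self):
        r = g_test(Contingency2x2(0, 500, 0, 700))
        assert r.g == 0.0 and r.p_chi2 == 1.0

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.integers(0, 30), b=st.integers(1, 30),
        c=st.integers(0, 30), d=st.integers(1, 30),
    )
    def test_uncorrected_matches_direct_formula_and_yates_shrinks(self, a, b, c, d):
        raw = g_test(Contingency2x2(a, b, c, d), yates=False)
        corrected = g_test(Contingency2x2(a, b, c, d), yates=True)
        if a + c > 0:
            assert raw.g == pytest.approx(g_direct(a, b, c, d), abs=1e-9)
        assert corrected.g <= raw.g + 1e-9

    def test_uncorrected_matches_scipy_log_likelihood(self):
        # independent implementation of the same statistic
        table = [[25, 7639], [17, 10958]]
        ours = g_test(Contingency2x2(25, 7639, 17, 10958), yates=False)
        g_ref, p_ref, _, _ = stats.chi2_contingency(
            table, correction=False, lambda_="log-likelihood"
        )
        assert ours.g == pytest.approx(g_ref, rel=1e-12)
        assert ours.p_chi2 == pytest.approx(p_ref, rel=1e-12)

    def test_invariance_under_group_swap(self):
        t1 = g_test(Contingency2x2(25, 7639, 3, 10972)).g
        t2 = g_test(Contingency2x2(3, 10972, 25, 7639)).g
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_asymptotic_agreement_with_pearson(self):
        # sampling around independence with expected counts >= 50 everywhere:
        # G and Pearson chi2 agree within 5% (they diverge only under strong
        # association, where both reject overwhelmingly anyway)
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 50:
            t1, t2 = rng.integers(5000, 20000, size=2)
            rate = rng.uniform(0.01, 0.3)
            a = rng.binomial(t1, rate)
            c = rng.binomial(t2, rate)
            n = t1 + t2
            e_min = min(
                (a + c) * t1, (a + c) * t2,
                (n - a - c) * t1, (n - a - c) * t2,
            ) / n
            g = g_test(Contingency2x2(a, t1 - a, c, t2 - c), yates=False).g
            chi2 = stats.chi2_contingency(
                [[a, t1 - a], [c, t2 - c]], correction=False
            )[0]
            if e_min < 50 or chi2 < 0.5:
                continue
            assert abs(g - chi2) / chi2 < 0.05
            checked += 1

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(-1, 5, 2, 3)


class TestChi2Tail:
    def test_zero_statistic(self):
        assert chi2_tail(0.0) == 1.0

    def test_critical_value_at_p05(self):
        assert 0.0499 <= chi2_tail(3.84) <= 0.0501

    def test_monotone_decreasing(self):
        g = np.linspace(0, 50, 200)
        p = chi2_tail(g)
        assert np.all(np.diff(p) < 0)

    def test_erfc_identity(self):
        # chi2(1 df) upper tail p = erfc(sqrt(g/2))
        for g in (0.5, 3.84, 10.0, 39.1):
            assert chi2_tail(g) == pytest.approx(math.erfc(math.sqrt(g / 2)),
                                                 rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chi2_tail(-0.1)


def hypergeom_pmf(a, row1, col1, n):
    """P(top-left cell = a) for fixed margins, by direct factorial evaluation."""
    return (
        math.comb(col1, a)
        * math.comb(n - col1, row1 - a)
        / math.comb(n, row1)
    )


class TestFisherExact:
    def test_balanced_2x2_enumeration(self):
        # margins (2,2|2,2): support a in {0,1,2}, masses (1/6, 4/6, 1/6)
        t = Contingency2x2(1, 1, 1, 1)
        assert fisher_exact(t, "two-sided") == pytest.approx(1.0)
        assert fisher_exact(t, "greater") == pytest.approx(5 / 6)

    def test_one_sided_matches_point_mass_sum(self):
        # table (3,7,1,9): one-sided tail = pmf(3) + pmf(4)
        t = Contingency2x2(3, 7, 1, 9)
        expected = sum(hypergeom_pmf(a, 10, 4, 20) for a in (3, 4))
        assert fisher_exact(t, "greater") == pytest.approx(expected, rel=1e-12)

    def test_exhaustive_enumeration_small_tables(self):
        # every table with n <= 18 and nondegenerate margins
        for n in range(2, 19):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        row1, col1 = a + b, a + c
                        support = range(
                            max(0, row1 + col1 - n), min(row1, col1) + 1
                        )
                        tail = sum(
                            hypergeom_pmf(k, row1, col1, n)
                            for k in support
                            if k >= a
                        )
                        got = fisher_exact(Contingency2x2(a, b, c, d), "greater")
                        assert got == pytest.approx(tail, rel=1e-9), (a, b, c, d)


class TestMannWhitney:
    def test_identical_samples(self):
        assert mann_whitney_exact([5, 6, 7], [5, 6, 7]) == pytest.approx(1.0)

    def test_complete_separation_3v3(self):
        # most extreme of C(6,3)=20 assignments, both tails: p = 2/20
        assert mann_whitney_exact([9, 9, 9], [0, 0, 0]) == pytest.approx(0.1)

    def test_two_vs_two(self):
        # enumeration of all C(4,2)=6 assignments gives 2/6
        assert mann_whitney_exact([3, 4], [1, 2]) == pytest.approx(1 / 3)

    def test_matches_brute_force_enumeration_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 5, size=4)
            b = rng.integers(0, 5, size=3)
            pooled = np.concatenate([a, b]).astype(float)
            ranks = stats.rankdata(pooled)
            w_obs = ranks[:4].sum()
            mean_w = 4 * (len(pooled) + 1) / 2
            hits = sum(
                1
                for idx in itertools.combinations(range(len(pooled)), 4)
                if abs(ranks[list(idx)].sum() - mean_w)
                >= abs(w_obs - mean_w) - 1e-9
            )
            expected = hits / math.comb(7, 4)
            assert mann_whitney_exact(a, b) == pytest.approx(expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1, 2])


class TestPairwiseDifferential:
    @pytest.fixture
    def two_group_pooled(self):
        samples = [SampleInfo("a1", "A", "pa", 1), SampleInfo("b1", "B", "pb", 1)]
        counts = np.array([[40, 2], [3, 45], [10, 10], [0, 0], [500, 520]])
        m = CountMatrix([f"P{i}" for i in range(5)], samples, counts)
        return pool_counts(m)

    def test_sorted_by_descending_rsc(self, two_group_pooled):
        res = pairwise_differential(two_group_pooled, ("A", "B"))
        rscs = [r.r_sc for r in res]
        assert rscs == sorted(rscs, reverse=True)

    def test_double_zero_protein_not_significant(self, two_group_pooled):
        res = {r.protein_id: r for r in pairwise_differential(
            two_group_pooled, ("A", "B"))}
        assert res["P3"].g == 0.0 and res["P3"].p == 1.0
        assert not res["P3"].significant and not res["P3"].candidate

    def test_candidate_needs_both_significance_and_fold(self, two_group_pooled):
        res = {r.protein_id: r for r in pairwise_differential(
            two_group_pooled, ("A", "B"))}
        assert res["P0"].candidate  # large fold, significant
        assert not res["P4"].candidate  # abundant but small fold

    def test_group_swap_negates_rsc_keeps_g(self, two_group_pooled):
        fwd = {r.protein_id: r for r in pairwise_differential(
            two_group_pooled, ("A", "B"))}
        rev = {r.protein_id: r for r in pairwise_differential(
            two_group_pooled, ("B", "A"))}
        for pid in fwd:
            assert fwd[pid].g == pytest.approx(rev[pid].g, rel=1e-12)
            assert fwd[pid].r_sc == pytest.approx(-rev[pid].r_sc, abs=1e-12)

    def test_unknown_pair_rejected(self, two_group_pooled):
        with pytest.raises(ValueError, match="unknown pair"):
            pairwise_differential(two_group_pooled, ("A", "Z"))

    def test_null_flagged_fraction_near_alpha_large_counts(self):
        # with large per-protein counts the Yates G-test is close to nominal
        rng = np.random.default_rng(42)
        n_prot = 2000
        lam = 200.0
        n_a = rng.poisson(lam, n_prot)
        n_b = rng.poisson(lam, n_prot)
        g = g_statistic(n_a, n_a.sum(), n_b, n_b.sum())
        frac = (stats.chi2.sf(g, 1) < 0.05).mean()
        assert 0.03 <= frac <= 0.07
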