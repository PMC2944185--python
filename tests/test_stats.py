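"""Statistical core: exact Fisher tests against independent oracles, BH,
hypergeometric tails, Kaplan-Meier and log-rank."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from glioprofile.stats import (SurvivalData, bh_adjust, fisher_exact_2x2,
                               fisher_exact_rxc, hypergeometric_tail,
                               km_estimator, logrank_test)


class TestFisher2x2:
    @pytest.mark.parametrize("table,printed", [
        ([[7, 1], [3, 8]], 0.02),    # classical: chemo 7/8 vs radio 3/11
        ([[8, 1], [23, 24]], 0.03),  # neural vs non-neural response rate
        ([[9, 2], [6, 11]], 0.02),   # EGFR amplicon 9/11 vs 6/17
        ([[5, 10], [8, 2]], 0.04),   # CD3+CD68 infiltration
    ])
    def test_published_tables_round_to_printed(self, table, printed):
        p, _ = fisher_exact_2x2(table)
        assert round(p, 2) == printed

    def test_p16_contrast_exact_value(self):
        p, odds = fisher_exact_2x2([[9, 2], [0, 17]])
        assert p == pytest.approx(7.963051e-6, rel=1e-6)
        assert np.isinf(odds)

    def test_balanced_table_p_one(self):
        p, odds = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0, abs=1e-12)
        assert odds == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 15, size=(2, 2))
        if t.sum() == 0:
            t[0, 0] = 1
        p_ours, odds = fisher_exact_2x2(t)
        res = sps.fisher_exact(t)
        assert p_ours == pytest.approx(res.pvalue, rel=1e-9)

    def test_probabilities_sum_to_one_over_margins(self):
        # hypergeometric masses over every margin-consistent table sum to 1
        for n in (8, 21, 41, 60):
            for row1 in (1, n // 3, n // 2):
                for col1 in (1, n // 4, n // 2):
                    lo = max(0, row1 + col1 - n)
                    hi = min(row1, col1)
                    pm = sps.hypergeom.pmf(np.arange(lo, hi + 1), n, col1, row1)
                    assert pm.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero grand total"):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestFisherRxc:
    @pytest.mark.parametrize("seed", range(10))
    def test_reduces_to_2x2(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 12, size=(2, 2))
        if t.sum() == 0:
            t[1, 1] = 2
        assert fisher_exact_rxc(t) == pytest.approx(
            fisher_exact_2x2(t)[0], abs=1e-12)

    def test_diagonal_identity_table(self):
        # both margin-consistent tables have probability 1/2
        assert fisher_exact_rxc([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_row_of_zeros_single_table(self):
        assert fisher_exact_rxc([[3, 2, 1], [0, 0, 0]]) == pytest.approx(
            1.0, abs=1e-12)

    def test_cd3_infiltration_2x3_vs_r_oracle(self):
        # frozen from R fisher.test(matrix(c(4,6,5,7,3,0), nrow=2, byrow=TRUE))
        p = fisher_exact_rxc([[4, 6, 5], [7, 3, 0]])
        assert p == pytest.approx(0.0461906, rel=1e-5)

    def test_large_total_advises_against_enumeration(self):
        with pytest.raises(ValueError, match="Monte Carlo"):
            fisher_exact_rxc([[100, 80], [60, 40]])


class TestBhAdjust:
    def test_direct_formula(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_q_dominates_p_and_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p[perm]), q[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestHypergeometricTail:
    def test_complete_overlap_example(self):
        # C(5,5) C(5,0) / C(10,5) = 1/252
        assert hypergeometric_tail(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_k_zero_is_one(self):
        assert hypergeometric_tail(40, 10, 8, 0) == 1.0

    def test_rational_enumeration_oracle(self):
        for N in (10, 17, 24, 30):
            for K in (2, N // 3, N // 2):
                for n in (3, N // 4, N // 2):
                    for k in range(0, min(K, n) + 1):
                        exact = sum(
                            Fraction(comb(K, i) * comb(N - K, n - i),
                                     comb(N, n))
                            for i in range(k, min(K, n) + 1))
                        assert hypergeometric_tail(N, K, n, k) == pytest.approx(
                            float(exact), rel=1e-12)

    def test_inconsistent_args_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(10, 12, 5, 2)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        sd = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1], ["a"] * 3)
        km = km_estimator(sd)
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert np.allclose(km.at_risk, [3, 2, 1])

    def test_all_censored_flat_curve(self):
        sd = SurvivalData([5.0, 8.0, 9.0], [0, 0, 0], ["a"] * 3)
        km = km_estimator(sd)
        assert len(km.event_times) == 0
        assert km.median is None

    def test_median_first_time_at_or_below_half(self):
        # S drops to 0.6 at t=5 and 0.4 at t=8: median is 8
        time = [5.0] * 2 + [8.0] + [20.0, 21.0]
        event = [1, 1, 1, 0, 0]
        km = km_estimator(SurvivalData(time, event, ["a"] * 5))
        assert km.median == 8.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5.0, size=40)
        km = km_estimator(SurvivalData(t, np.ones(40, int), ["a"] * 40))
        srt = np.sort(t)
        for tt, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((srt > tt).mean(), abs=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalData([0.0, 1.0], [1, 1], ["a", "a"])


def _oe_statistic(times, events, grp, level):
    """Independent O-E / V log-rank statistic (hypergeometric variance)."""
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at = times >= t
        n, n1 = at.sum(), (at & (grp == level)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (grp == level)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_p_one(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        sd = SurvivalData(t, np.ones(6, int), ["a"] * 3 + ["b"] * 3)
        chi2, p = logrank_test(sd)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_statistic_matches_independent_formula(self):
        times = np.array([2., 3., 5., 7., 9., 4., 8., 12., 14., 20.])
        ev = np.ones(10, int)
        g = np.array(["a"] * 5 + ["b"] * 5)
        chi2, _ = logrank_test(SurvivalData(times, ev, g))
        assert chi2 == pytest.approx(_oe_statistic(times, ev, g, "a"),
                                     rel=1e-9)

    def test_permutation_oracle_ten_subjects(self):
        times = np.array([2., 3., 5., 7., 9., 4., 8., 12., 14., 20.])
        ev = np.ones(10, int)
        g = np.array(["a"] * 5 + ["b"] * 5)
        _, p_asym = logrank_test(SurvivalData(times, ev, g))
        obs = _oe_statistic(times, ev, g, "a")
        rng = np.random.default_rng(5)
        hits = sum(_oe_statistic(times, ev, rng.permutation(g), "a")
                   >= obs - 1e-12 for _ in range(20_000))
        p_perm = hits / 20_000
        # asymptotic chi-square vs exact permutation null at n=10: the gap
        # includes the approximation error, not just Monte-Carlo noise
        assert abs(p_asym - p_perm) < 0.05

    def test_time_scale_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, size=20)
        ev = rng.integers(0, 2, size=20)
        ev[0] = 1
        g = np.array(["a"] * 10 + ["b"] * 10)
        c1, p1 = logrank_test(SurvivalData(t, ev, g))
        c2, p2 = logrank_test(SurvivalData(t * 7.3, ev, g))
        assert c1 == pytest.approx(c2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_requires_two_groups(self):
        sd = SurvivalData([1.0, 2.0], [1, 1], ["a", "a"])
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(sd)
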