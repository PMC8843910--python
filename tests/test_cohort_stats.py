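"""First-principles statistics vs. hand calculations and independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from clonecomp import (
    NOT_REACHED,
    ContingencyTable2x2,
    SurvivalSample,
    build_contingency,
    fisher_exact_two_sided,
    km_curve,
    km_median,
    logrank_test,
    mann_whitney_u,
)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_matches_scipy_on_random_small_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
                continue
            ours = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_symmetries(self):
        t = ContingencyTable2x2(3, 9, 11, 2)
        p = fisher_exact_two_sided(t)
        swapped_rows = ContingencyTable2x2(11, 2, 3, 9)
        swapped_cols = ContingencyTable2x2(9, 3, 2, 11)
        transposed = ContingencyTable2x2(3, 11, 9, 2)
        for variant in (swapped_rows, swapped_cols, transposed):
            assert fisher_exact_two_sided(variant) == pytest.approx(p, rel=1e-12)

    def test_matches_full_enumeration_oracle(self):
        """Sum over the entire hypergeometric support computed from factorials."""
        def oracle(a, b, c, d):
            n = a + b + c + d
            row1, col1 = a + b, a + c
            def point(x):
                return (math.comb(row1, x) * math.comb(n - row1, col1 - x)
                        / math.comb(n, col1))
            p_obs = point(a)
            return sum(point(x)
                       for x in range(max(0, col1 - (n - row1)),
                                      min(row1, col1) + 1)
                       if point(x) <= p_obs * (1 + 1e-7))

        rng = np.random.default_rng(23)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 11, size=4)
            ours = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            assert ours == pytest.approx(oracle(a, b, c, d), rel=1e-9)


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n^2 / 2
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    def test_exact_matches_enumeration(self):
        """For pooled n <= 12, p equals direct enumeration over subsets."""
        x = [1.2, 3.4, 5.1, 2.2]
        y = [0.5, 4.4, 6.0, 7.7, 8.1]
        u_obs, p = mann_whitney_u(x, y)
        pooled = np.array(x + y)
        ranks = scipy.stats.rankdata(pooled)
        n1 = len(x)
        mu = n1 * len(y) / 2
        us = [sum(ranks[list(i)]) - n1 * (n1 + 1) / 2
              for i in itertools.combinations(range(len(pooled)), n1)]
        expected = np.mean(np.abs(np.array(us) - mu) >= abs(u_obs - mu) - 1e-9)
        assert p == pytest.approx(expected)

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 55)
        u, p = mann_whitney_u(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(1, 20)
        y = rng.exponential(2, 25)
        u1, p1 = mann_whitney_u(x, y)
        u2, p2 = mann_whitney_u(np.log(x), np.log(y))
        assert (u1, p1) == (u2, p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        curve = km_curve([SurvivalSample(t, True) for t in (1, 2, 3, 4)])
        assert curve.survival == pytest.approx((0.75, 0.5, 0.25, 0.0))
        assert km_median(curve) == 2

    def test_all_censored_flat_at_one(self):
        curve = km_curve([SurvivalSample(t, False) for t in (1, 2, 3)])
        assert curve.event_times == ()
        assert km_median(curve) == NOT_REACHED

    def test_hand_product_limit_with_censoring(self):
        # {1+, 2, 3+}: only t=2 is an event, 2 at risk there -> S(2) = 0.5
        curve = km_curve([SurvivalSample(1, False), SurvivalSample(2, True),
                          SurvivalSample(3, False)])
        assert curve.survival == pytest.approx((0.5,))
        assert km_median(curve) == 2

    def test_single_event(self):
        assert km_median(km_curve([SurvivalSample(5, True)])) == 5

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(10, 200)
        curve = km_curve([SurvivalSample(float(t), True) for t in times])
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(np.mean(times > t))

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(13)
        t = rng.exponential(10, 100)
        e = rng.random(100) < 0.7
        curve = km_curve([SurvivalSample(float(a), bool(b))
                          for a, b in zip(t, e)])
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(et).iloc[0]))

    def test_non_positive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalSample(0.0, True)


class TestLogRank:
    def test_identical_groups_null(self):
        g = [SurvivalSample(t, True) for t in (1, 2, 3)]
        chi2, p = logrank_test(g, g)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_calculation_two_patients(self):
        chi2, p = logrank_test([SurvivalSample(1, True)],
                               [SurvivalSample(2, True)])
        assert chi2 == pytest.approx(1.0)          # (O-E)^2/V = 0.25/0.25
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([SurvivalSample(1, False)], [SurvivalSample(2, False)])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(14)
        a = [SurvivalSample(float(t), bool(e))
             for t, e in zip(rng.exponential(10, 60), rng.random(60) < 0.8)]
        b = [SurvivalSample(float(t), bool(e))
             for t, e in zip(rng.exponential(18, 70), rng.random(70) < 0.8)]
        chi2, p = logrank_test(a, b)
        ref = ll_logrank([s.time for s in a], [s.time for s in b],
                         [s.event for s in a], [s.event for s in b])
        assert chi2 == pytest.approx(ref.test_statistic)
        assert p == pytest.approx(ref.p_value)

    def test_type_one_error_calibrated(self):
        """Equal exponential arms, n=200 each: rejection rate at alpha=0.05
        over 1,000 seeded replicates stays within [0.03, 0.07]."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(1000):
            a = [SurvivalSample(float(t), True)
                 for t in rng.exponential(10, 200)]
            b = [SurvivalSample(float(t), True)
                 for t in rng.exponential(10, 200)]
            rejections += logrank_test(a, b)[1] < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_null_p_uniform_under_permutation(self):
        """Label permutations of one pooled sample give uniform p-values."""
        rng = np.random.default_rng(15)
        times = rng.exponential(10, 60)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(60)
            a = [SurvivalSample(float(times[i]), True) for i in perm[:30]]
            b = [SurvivalSample(float(times[i]), True) for i in perm[30:]]
            ps.append(logrank_test(a, b)[1])
        ks = scipy.stats.kstest(ps, "uniform").statistic
        assert ks < 0.05


class TestBuildContingency:
    def test_counts_by_group_and_outcome(self):
        df = pd.DataFrame({
            "cc": ["mono"] * 8 + ["poly"] * 26,
            "recur": [1] * 2 + [0] * 6 + [1] * 20 + [0] * 6,
        })
        t = build_contingency(df, "cc", "recur")
        assert (t.a, t.b, t.c, t.d) == (6, 2, 6, 20)  # levels sorted: 0 first
        assert fisher_exact_two_sided(t) == pytest.approx(0.0127, abs=5e-5)

    def test_missing_values_dropped_with_warning(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"],
                           "o": [1.0, np.nan, 0.0, 1.0]})
        with pytest.warns(UserWarning, match="dropping 1"):
            t = build_contingency(df, "g", "o")
        assert t.total == 3

    def test_non_binary_field_rejected(self):
        df = pd.DataFrame({"g": ["a", "b", "c"], "o": [0, 1, 0]})
        with pytest.raises(ValueError, match="binary"):
            build_contingency(df, "g", "o")

    def test_empty_table_rejected(self):
        df = pd.DataFrame({"g": [np.nan], "o": [np.nan]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                build_contingency(df, "g", "o")
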