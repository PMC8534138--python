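import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nbith.survival import (
    SurvivalRecord,
    km_estimate,
    logrank,
    logrank_from_arrays,
    pearson_chi2,
    sca_quartile_test,
    survival_at,
)


def rec(case_id, t, event, endpoint="os"):
    if endpoint == "os":
        return SurvivalRecord(case_id, t, event, t, event)
    return SurvivalRecord(case_id, t, event, t, False)


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        curve = km_estimate([rec(str(i), t, False) for i, t in
                             enumerate([5, 10, 20])])
        assert survival_at(curve, 0) == 1.0
        assert survival_at(curve, 100) == 1.0

    def test_hand_product_limit(self):
        # event at 2 (3 at risk), censored at 3, event at 4 (1 at risk)
        records = [rec("a", 2, True), rec("b", 3, False), rec("c", 4, True)]
        curve = km_estimate(records)
        assert survival_at(curve, 2) == pytest.approx(2 / 3)
        assert survival_at(curve, 3) == pytest.approx(2 / 3)
        assert survival_at(curve, 4) == pytest.approx(0.0)
        assert survival_at(curve, 1.99) == 1.0

    def test_ties_events_before_censorings(self):
        # a censoring tied with an event is still at risk at that time
        records = [rec("a", 5, True), rec("b", 5, False), rec("c", 9, False)]
        curve = km_estimate(records)
        assert survival_at(curve, 5) == pytest.approx(2 / 3)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=40).round(2)
        records = [rec(str(i), t, True) for i, t in enumerate(times)]
        curve = km_estimate(records)
        for t in (1.0, 5.0, 15.0):
            assert survival_at(curve, t) == pytest.approx(
                np.mean(times > t), abs=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        times = rng.exponential(20, size=60).round(1)
        events = rng.uniform(size=60) < 0.7
        records = [rec(str(i), t, bool(e)) for i, (t, e) in
                   enumerate(zip(times, events))]
        curve = km_estimate(records)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in (5, 10, 30, 60):
            assert survival_at(curve, t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rec("a", -1, True)

    @given(st.lists(st.tuples(st.floats(0, 100), st.booleans()),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_curve_monotone_in_unit_interval(self, data):
        records = [rec(str(i), round(t, 3), e) for i, (t, e) in enumerate(data)]
        curve = km_estimate(records)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))


class TestLogRank:
    def test_identical_groups_null(self):
        group = [rec(str(i), t, True) for i, t in enumerate([3, 6, 9])]
        res = logrank(group, list(group))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # group A events at 1, 2; group B censored at 3, 3:
        # O-E = 7/6, Var = 17/36, chi2 = (7/6)^2 / (17/36) ~ 2.882
        a = [rec("a1", 1, True), rec("a2", 2, True)]
        b = [rec("b1", 3, False), rec("b2", 3, False)]
        res = logrank(a, b)
        assert res.chi2 == pytest.approx((7 / 6) ** 2 / (17 / 36))
        assert res.chi2 == pytest.approx(2.88, abs=0.01)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(3)
        for _ in range(5):
            ta = rng.exponential(15, 25).round(1)
            tb = rng.exponential(25, 30).round(1)
            ea = rng.uniform(size=25) < 0.8
            eb = rng.uniform(size=30) < 0.8
            mine = logrank_from_arrays(ta, ea, tb, eb)
            ref = logrank_test(ta, tb, ea, eb)
            assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_p_undefined(self):
        a = [rec("a", 5, False)]
        b = [rec("b", 7, False)]
        with pytest.warns(UserWarning, match="no events"):
            res = logrank(a, b)
        assert res.p_value is None

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [rec("b", 1, True)])

    def test_agrees_with_permutation_small_sample(self):
        """Asymptotic p agrees with an exact label-permutation distribution
        of the statistic on a small two-group sample."""
        import itertools

        rng = np.random.default_rng(11)
        times = np.round(rng.exponential(10, 10), 1)
        events = np.ones(10, dtype=bool)
        obs = logrank_from_arrays(times[:5], events[:5], times[5:], events[5:])
        stat_ge = 0
        n_perm = 0
        for idx in itertools.combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(idx)] = True
            res = logrank_from_arrays(times[mask], events[mask],
                                      times[~mask], events[~mask])
            stat_ge += res.chi2 >= obs.chi2 - 1e-12
            n_perm += 1
        p_perm = stat_ge / n_perm
        assert obs.p_value == pytest.approx(p_perm, abs=0.08)


class TestPearsonChi2:
    def test_independent_table_zero(self):
        stat, df, p = pearson_chi2(np.array([[5, 5], [5, 5]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        stat, df, p = pearson_chi2(np.array([[10, 0], [0, 10]]))
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_2x2_closed_form(self):
        # N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 12, 5, 3, 9
        stat, _, _ = pearson_chi2(np.array([[a, b], [c, d]]))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(closed)

    def test_matches_scipy(self):
        table = np.array([[8, 2, 5], [3, 7, 6]])
        stat, df, p = pearson_chi2(table)
        ref = stats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue)

    def test_continuity_correction_flag(self):
        table = np.array([[8, 2], [3, 7]])
        stat_c, _, _ = pearson_chi2(table, continuity_correction=True)
        ref = stats.chi2_contingency(table, correction=True)
        assert stat_c == pytest.approx(ref.statistic)

    def test_zero_margin_dropped_with_warning(self):
        table = np.array([[5, 0, 5], [3, 0, 7]])
        with pytest.warns(UserWarning, match="zero marginal"):
            stat, df, _ = pearson_chi2(table)
        assert df == 1

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2(np.array([[1, 2]]))


class TestQuartileTest:
    def test_identical_distributions_high_p(self):
        counts = list(range(1, 21))
        cases = [("A", c) for c in counts] + [("B", c) for c in counts]
        _, _, p = sca_quartile_test(cases)
        assert p > 0.9

    def test_disjoint_groups_match_hand_binning(self):
        lo = [("A", c) for c in range(1, 21)]       # 1..20
        hi = [("B", c) for c in range(31, 51)]      # 31..50
        stat, df, p = sca_quartile_test(lo + hi)
        counts = np.array([c for _, c in lo + hi])
        q1, q2, q3 = np.quantile(counts, [0.25, 0.5, 0.75])
        table = np.zeros((2, 4), dtype=int)
        for g, c in lo + hi:
            b = sum(bound < c for bound in (q1, q2, q3))
            table[0 if g == "A" else 1, b] += 1
        ref_stat, ref_df, _ = pearson_chi2(table)
        assert stat == pytest.approx(ref_stat)
        assert df == ref_df

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            sca_quartile_test([("A", 3), ("A", 5)])

    def test_few_distinct_counts_falls_back(self):
        cases = [("A", 1)] * 5 + [("A", 2)] * 5 + [("B", 1)] * 3 + [("B", 2)] * 7
        with pytest.warns(UserWarning, match="distinct"):
            stat, df, p = sca_quartile_test(cases)
        assert df == 1
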