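import numpy as np
import pytest

from nbith.events import GenomicEvent
from nbith.genome import EventCallingConfig
from nbith.heterogeneity import (
    SampleProfile,
    brute_force_match,
    cohort_summary,
    infer_design,
    match_case,
    reciprocal_overlap,
)


def sca(sample, chrom, arm, direction, start, end, n_breaks=1, **kw):
    return GenomicEvent(sample, f"sca_{direction}", chrom, start, end,
                        arm=arm, direction=direction, n_breaks=n_breaks, **kw)


def profile(sample_id, events, case="c1", stype="T1"):
    return SampleProfile(sample_id, case, stype, tuple(events))


FOUR_SCAS = [
    ("17", "17q", "gain", 30_000_000, 60_000_000),
    ("11", "11q", "loss", 60_000_000, 100_000_000),
    ("1", "1p", "loss", 10_000_000, 50_000_000),
    ("2", "2p", "gain", 5_000_000, 40_000_000),
]


class TestMatchCase:
    def test_identical_profiles_no_difference(self):
        evs = lambda s: [sca(s, *row) for row in FOUR_SCAS]
        cc = match_case([profile("a", evs("a")),
                         profile("b", evs("b"), stype="T2")])
        assert cc.n_total_events == 4
        assert cc.n_diff_events == 0
        assert not cc.ith and cc.high_ith is None

    def test_all_private_is_fully_heterogeneous(self):
        # one aberration-free sample against four SCAs: 4/4 = 100%
        cc = match_case([
            profile("a", []),
            profile("b", [sca("b", *row) for row in FOUR_SCAS], stype="T2"),
        ])
        assert (cc.n_total_events, cc.n_diff_events) == (4, 4)
        assert cc.pct_diff == pytest.approx(100.0)
        assert cc.ith and cc.high_ith

    def test_half_differing_is_high_ith_inclusive(self):
        # 2 of 4 events differ: exactly 50% classifies as high ITH
        shared = [sca("a", *row) for row in FOUR_SCAS[:2]]
        private = [sca("a", *row) for row in FOUR_SCAS[2:]]
        mirrored = [sca("b", *row) for row in FOUR_SCAS[:2]]
        cc = match_case([profile("a", shared + private),
                         profile("b", mirrored, stype="T2")])
        assert (cc.n_total_events, cc.n_diff_events) == (4, 2)
        assert cc.pct_diff == pytest.approx(50.0)
        assert cc.high_ith

    def test_breakpoint_shift_detected(self):
        # same 17q gain, start differing by 8 Mb (> 5 Mb tolerance) while
        # reciprocal overlap stays >= 0.5: one cluster, one differing event
        a = sca("a", "17", "17q", "gain", 30_000_000, 80_000_000)
        b = sca("b", "17", "17q", "gain", 38_000_000, 80_000_000)
        cc = match_case([profile("a", [a]), profile("b", [b], stype="T2")])
        (cluster,) = cc.clusters
        assert cluster.shift and not cluster.extra_breaks
        assert (cc.n_total_events, cc.n_diff_events) == (1, 1)

    def test_extra_breaks_detected(self):
        a = sca("a", "17", "17q", "gain", 30_000_000, 80_000_000, n_breaks=1)
        b = sca("b", "17", "17q", "gain", 30_000_000, 80_000_000, n_breaks=3)
        cc = match_case([profile("a", [a]), profile("b", [b], stype="T2")])
        assert cc.clusters[0].extra_breaks
        assert cc.n_diff_events == 1

    def test_low_overlap_splits_into_private_clusters(self):
        a = sca("a", "17", "17q", "gain", 28_000_000, 45_000_000)
        b = sca("b", "17", "17q", "gain", 60_000_000, 80_000_000)
        cc = match_case([profile("a", [a]), profile("b", [b], stype="T2")])
        assert cc.n_total_events == 2 and cc.n_diff_events == 2

    def test_mycn_amplification_not_counted(self):
        amp = GenomicEvent("a", "amplification", "2", 15_900_000, 16_100_000,
                           arm="2p", direction="gain", gene="MYCN",
                           counted=False)
        amp_b = GenomicEvent("b", "amplification", "2", 15_900_000, 16_100_000,
                             arm="2p", direction="gain", gene="MYCN",
                             counted=False)
        ev = [sca("a", *FOUR_SCAS[0])]
        cc = match_case([profile("a", ev + [amp]),
                         profile("b", [amp_b], stype="T2")])
        assert cc.n_total_events == 1  # the 17q gain only
        assert cc.n_diff_events == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        profs = [
            profile("a", [sca("a", *row) for row in FOUR_SCAS]),
            profile("b", [sca("b", *row) for row in FOUR_SCAS[:2]], stype="T2"),
            profile("c", [sca("c", *row) for row in FOUR_SCAS[1:]], stype="LBp"),
        ]
        ref = match_case(profs)
        for _ in range(5):
            perm = [profs[i] for i in rng.permutation(3)]
            cc = match_case(perm)
            assert (cc.n_total_events, cc.n_diff_events, cc.ith,
                    cc.high_ith) == (ref.n_total_events, ref.n_diff_events,
                                     ref.ith, ref.high_ith)

    def test_self_comparison_is_homogeneous(self):
        evs = [sca("a", *row) for row in FOUR_SCAS]
        dup = [sca("b", *row) for row in FOUR_SCAS]
        cc = match_case([profile("a", evs), profile("b", dup, stype="T2")])
        assert cc.n_diff_events == 0 and not cc.ith

    def test_single_profile_warns_degenerate(self):
        with pytest.warns(UserWarning, match="single sample"):
            cc = match_case([profile("a", [sca("a", *FOUR_SCAS[0])])])
        assert not cc.ith and cc.n_diff_events == 0

    def test_mixed_cases_rejected(self):
        with pytest.raises(ValueError, match="mixed cases"):
            match_case([profile("a", [], case="c1"),
                        profile("b", [], case="c2")])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            match_case([])

    def test_no_events_pct_undefined(self):
        cc = match_case([profile("a", []), profile("b", [], stype="T2")])
        assert cc.n_total_events == 0
        assert cc.pct_diff is None and not cc.ith


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 100), (0, 100), 1.0),
            ((0, 100), (50, 150), 0.5),
            ((0, 100), (100, 200), 0.0),
            ((0, 200), (50, 150), 0.5),
        ],
    )
    def test_values(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)
        assert reciprocal_overlap(b, a) == pytest.approx(expected)


class TestInferDesign:
    @pytest.mark.parametrize(
        "types, design",
        [
            (["T1", "T2"], "T+T"),
            (["T1", "LBp"], "T+LB"),
            (["T1", "T2", "LBp"], "T+T+LB"),
            (["LBp", "LBm"], "LB+LB"),
            (["T1", "T2", "T3", "LBp"], "T+T+LB"),
        ],
    )
    def test_designs(self, types, design):
        assert infer_design(types) == design


class TestCohortSummary:
    def test_empty(self):
        assert cohort_summary([]).empty

    def test_groups_and_means(self):
        comparisons = []
        for i, (tot, diff) in enumerate([(4, 4), (10, 1), (8, 0)]):
            evs_a = [sca("a", *FOUR_SCAS[0])]
            cc = match_case([profile("a", evs_a, case=f"c{i}"),
                             profile("b", [], case=f"c{i}", stype="T2")])
            # patch the counted numbers to exercise the summary arithmetic
            cc.n_total_events, cc.n_diff_events = tot, diff
            cc.pct_diff = 100.0 * diff / tot
            cc.ith = diff > 0
            comparisons.append(cc)
        summary = cohort_summary(comparisons)
        row = summary[summary.mycn_status == "all"].iloc[0]
        assert row.n_cases == 3 and row.n_ith == 2
        assert row.mean_diff == pytest.approx((4 + 1) / 2)
        assert row.mean_total == pytest.approx((4 + 10) / 2)
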