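import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbith.events import GenomicEvent, SegmentRecord, extract_events, sca_count
from nbith.genome import EventCallingConfig


def seg(chrom, start, end, cn, sample="s1", loh=False):
    return SegmentRecord(sample, chrom, start, end, cn, loh)


class TestExtractEvents:
    def test_baseline_profile_yields_nothing(self, genome, cfg):
        segs = [seg("1", 0, 50_000_000, 2), seg("7", 10_000_000, 90_000_000, 2)]
        assert extract_events(segs, genome, cfg) == []

    def test_17q_gain_is_typical_sca(self, genome, cfg):
        arm = genome.arms["17q"]
        segs = [seg("17", arm.start + 5_000_000, arm.start + 25_000_000, 3)]
        (ev,) = extract_events(segs, genome, cfg)
        assert ev.event_class == "sca_gain"
        assert ev.arm == "17q"
        assert ev.catalog_label == "typical"
        assert ev.n_breaks == 1

    def test_focal_tert_loss_is_fsca_not_sca(self, genome, cfg):
        _, gs, ge = genome.gene_catalog["TERT"]
        segs = [seg("5", gs - 500_000, gs + 1_500_000, 1)]
        (ev,) = extract_events(segs, genome, cfg)
        assert ev.event_class == "fsca"
        assert ev.gene == "TERT"
        assert ev.direction == "loss"

    def test_whole_chromosome_gain_is_numerical(self, genome, cfg):
        length = genome.chromosomes["7"].length
        segs = [seg("7", 0, int(length * 0.99), 3)]
        assert extract_events(segs, genome, cfg) == []

    def test_oscillating_chromosome_is_ctlp(self, genome, cfg):
        # 12 alternating 2<->1 segments confined to 3p; individually focal,
        # so only the chromothripsis-like pattern is emitted
        segs = [
            seg("3", 1_000_000 + i * 200_000, 1_000_000 + (i + 1) * 200_000,
                2 if i % 2 == 0 else 1)
            for i in range(12)
        ]
        (ev,) = extract_events(segs, genome, cfg)
        assert ev.event_class == "ctlp"
        assert ev.n_breaks >= cfg.ctlp_min_switches

    def test_exactly_3mb_is_segmental(self, genome, cfg):
        arm = genome.arms["4p"]
        segs = [seg("4", arm.start, arm.start + 3_000_000, 1)]
        (ev,) = extract_events(segs, genome, cfg)
        assert ev.event_class == "sca_loss"

    def test_just_below_3mb_over_no_gene_drops(self, genome, cfg):
        arm = genome.arms["4p"]
        segs = [seg("4", arm.start, arm.start + 2_999_999, 1)]
        assert extract_events(segs, genome, cfg) == []

    def test_fragmented_arm_counts_breaks(self, genome, cfg):
        arm = genome.arms["11q"]
        segs = [
            seg("11", arm.start + 1_000_000, arm.start + 6_000_000, 1),
            seg("11", arm.start + 10_000_000, arm.start + 16_000_000, 1),
        ]
        (ev,) = extract_events(segs, genome, cfg)
        assert ev.event_class == "sca_loss" and ev.n_breaks == 2
        assert (ev.start, ev.end) == (arm.start + 1_000_000, arm.start + 16_000_000)

    def test_cnloh_requires_baseline_cn_and_size(self, genome, cfg):
        segs = [
            seg("9", 1_000_000, 15_000_000, 2, loh=True),
            seg("10", 1_000_000, 5_000_000, 2, loh=True),  # too short
            seg("2", 1_000_000, 15_000_000, 1, loh=True),  # a loss, not cnLOH
        ]
        events = extract_events(segs, genome, cfg)
        cnloh = [e for e in events if e.event_class == "cnloh"]
        assert len(cnloh) == 1 and cnloh[0].chrom == "9"

    def test_mycn_amplification_tagged_not_counted(self, genome, cfg):
        _, gs, ge = genome.gene_catalog["MYCN"]
        segs = [seg("2", gs - 100_000, ge + 100_000, 30)]
        (ev,) = extract_events(segs, genome, cfg)
        assert ev.event_class == "amplification"
        assert ev.gene == "MYCN"
        assert not ev.counted

    def test_amp_within_gain_stays_one_sca(self, genome, cfg):
        # a 2p gain containing a MYCN amplification is one contiguous SCA
        _, gs, ge = genome.gene_catalog["MYCN"]
        segs = [
            seg("2", 5_000_000, gs, 3),
            seg("2", gs, ge, 30),
            seg("2", ge, 40_000_000, 3),
        ]
        events = extract_events(segs, genome, cfg)
        scas = [e for e in events if e.event_class == "sca_gain"]
        amps = [e for e in events if e.event_class == "amplification"]
        assert len(scas) == 1 and scas[0].n_breaks == 1
        assert len(amps) == 1 and not amps[0].counted

    def test_overlapping_segments_rejected(self, genome, cfg):
        segs = [seg("1", 0, 10_000_000, 3), seg("1", 5_000_000, 15_000_000, 3)]
        with pytest.raises(ValueError, match="overlapping"):
            extract_events(segs, genome, cfg)

    def test_unknown_chromosome_rejected(self, genome, cfg):
        with pytest.raises(ValueError, match="unknown chromosome"):
            extract_events([seg("chr99", 0, 1_000_000, 3)], genome, cfg)

    def test_beyond_bounds_rejected(self, genome, cfg):
        with pytest.raises(ValueError, match="beyond"):
            extract_events([seg("21", 0, 99_000_000_000, 3)], genome, cfg)

    def test_deterministic_ordering(self, genome, cfg):
        segs = [
            seg("17", 30_000_000, 60_000_000, 3),
            seg("1", 10_000_000, 40_000_000, 1),
            seg("11", 80_000_000, 100_000_000, 1),
        ]
        ev1 = extract_events(segs, genome, cfg)
        ev2 = extract_events(list(reversed(segs)), genome, cfg)
        assert ev1 == ev2
        assert [e.chrom for e in ev1] == ["1", "11", "17"]


class TestSizeThresholdMonotonicity:
    @given(st.integers(min_value=1, max_value=40))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_raising_min_sca_size_never_adds_events(self, genome, mb):
        segs = [
            seg("17", 30_000_000, 30_000_000 + mb * 1_000_000, 3),
            seg("4", 1_000_000, 1_000_000 + mb * 500_000, 1),
        ]
        small = EventCallingConfig(min_sca_size=3_000_000)
        large = EventCallingConfig(min_sca_size=10_000_000)
        n_small = sca_count(extract_events(segs, genome, small))
        n_large = sca_count(extract_events(segs, genome, large))
        assert n_large <= n_small

    def test_raising_whole_chrom_fraction_never_drops_events(self, genome):
        length = genome.chromosomes["7"].length
        segs = [seg("7", 0, int(length * 0.93), 3)]
        loose = EventCallingConfig(whole_chrom_fraction=0.90)
        strict = EventCallingConfig(whole_chrom_fraction=0.99)
        assert sca_count(extract_events(segs, genome, loose)) <= sca_count(
            extract_events(segs, genome, strict)
        )


class TestScaCount:
    def test_empty(self):
        assert sca_count([]) == 0

    def test_excludes_non_sca_classes(self, genome):
        events = [
            GenomicEvent("s1", "sca_gain", "17", 30_000_000, 60_000_000,
                         arm="17q", direction="gain"),
            GenomicEvent("s1", "sca_loss", "11", 60_000_000, 100_000_000,
                         arm="11q", direction="loss"),
            GenomicEvent("s1", "fsca", "5", 1_200_000, 1_400_000,
                         arm="5p", direction="gain", gene="TERT"),
            GenomicEvent("s1", "cnloh", "9", 0, 20_000_000, arm="9p"),
        ]
        assert sca_count(events) == 2

    def test_breaks_do_not_multiply(self):
        ev = GenomicEvent("s1", "sca_gain", "17", 30_000_000, 60_000_000,
                          arm="17q", direction="gain", n_breaks=3)
        assert sca_count([ev]) == 1

    def test_gain_and_loss_on_same_arm_count_twice(self):
        events = [
            GenomicEvent("s1", "sca_gain", "2", 0, 20_000_000,
                         arm="2p", direction="gain"),
            GenomicEvent("s1", "sca_loss", "2", 25_000_000, 45_000_000,
                         arm="2p", direction="loss"),
        ]
        assert sca_count(events) == 2


class TestRecordValidation:
    def test_segment_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            SegmentRecord("s", "1", 100, 100, 2)

    def test_event_requires_gene_for_fsca(self):
        with pytest.raises(ValueError, match="gene"):
            GenomicEvent("s", "fsca", "5", 0, 100, arm="5p", direction="gain")
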