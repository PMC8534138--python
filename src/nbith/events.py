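"""Genomic-event calling from one sample's segmented copy-number profile.

A segmented profile is reduced to the event vocabulary used for spatial
heterogeneity analysis in neuroblastoma:

* ``sca_gain`` / ``sca_loss`` — segmental chromosomal aberration of an arm
  (total aberrant length on the arm >= 3 Mb by default), excluding
  numerical whole-chromosome changes;
* ``fsca`` — focal aberration (< 3 Mb) over a catalogue gene (TERT, ATRX);
* ``cnloh`` — copy-neutral loss of heterozygosity (LOH at baseline copy
  number, >= 10 Mb by default);
* ``ctlp`` — chromothripsis-like pattern: many copy-number oscillations
  among few states confined to one chromosome;
* ``amplification`` — copy number >= 4x ploidy; amplification of MYCN (or
  ALK) is tagged and excluded from downstream event counting.

Baseline is a configured ploidy (diploid by default), never inferred from
the sample: gain means total_cn above baseline, loss below.  Uncovered
stretches of a chromosome are implicitly baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome import EventCallingConfig, GenomeModel

logger = logging.getLogger(__name__)

__all__ = ["SegmentRecord", "GenomicEvent", "extract_events", "sca_count"]

EVENT_CLASSES = ("sca_gain", "sca_loss", "fsca", "cnloh", "ctlp", "amplification")

#: amplifications of these genes are annotated but never counted as events
EXCLUDED_AMP_GENES = frozenset({"MYCN", "ALK"})


@dataclass(frozen=True)
class SegmentRecord:
    """One segmented copy-number interval (0-based, half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: int
    loh: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicEvent:
    sample_id: str
    event_class: str
    chrom: str
    start: int
    end: int
    arm: str | None = None  # None only for a ctlp spanning both arms
    direction: str | None = None  # gain / loss; None for cnloh, ctlp
    gene: str | None = None
    n_breaks: int = 1
    catalog_label: str = "not-applicable"
    counted: bool = True  # False for MYCN/ALK amplification

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.event_class == "fsca" and self.gene is None:
            raise ValueError("fsca events must carry a gene")
        if self.n_breaks < 1:
            raise ValueError("n_breaks must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def signed_arm(self) -> str | None:
        if self.arm is None or self.direction is None:
            return None
        from .genome import format_signed_arm

        return format_signed_arm(self.arm, self.direction)


def _state(cn: int, ploidy: int) -> str:
    if cn > ploidy:
        return "gain"
    if cn < ploidy:
        return "loss"
    return "neutral"


def _validate_segments(
    segments: list[SegmentRecord], genome: GenomeModel
) -> dict[str, list[SegmentRecord]]:
    samples = {s.sample_id for s in segments}
    if len(samples) > 1:
        raise ValueError(f"segments from multiple samples: {sorted(samples)}")
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        if seg.chrom not in genome.chromosomes:
            raise ValueError(f"unknown chromosome {seg.chrom!r}")
        if seg.end > genome.chromosomes[seg.chrom].length:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} beyond "
                f"chromosome end {genome.chromosomes[seg.chrom].length}"
            )
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
    return by_chrom


def _merge_runs(
    segs: list[SegmentRecord], ploidy: int
) -> list[tuple[str, int, int]]:
    """Maximal runs of identical aberration state among touching segments.

    Returns (state, start, end) for aberrant runs only.  Segments separated
    by an uncovered gap are implicitly separated by baseline.
    """
    runs: list[tuple[str, int, int]] = []
    for seg in segs:
        st = _state(seg.total_cn, ploidy)
        if st == "neutral":
            continue
        if runs and runs[-1][0] == st and runs[-1][2] == seg.start:
            runs[-1] = (st, runs[-1][1], seg.end)
        else:
            runs.append((st, seg.start, seg.end))
    return runs


def _split_at_arms(
    run: tuple[str, int, int], genome: GenomeModel, chrom: str
) -> list[tuple[str, str, int, int]]:
    """Intersect an aberrant run with the chromosome's arm intervals."""
    out = []
    for arm in genome.chrom_arms(chrom):
        s = max(run[1], arm.start)
        e = min(run[2], arm.end)
        if s < e:
            out.append((arm.name, run[0], s, e))
    return out


def extract_events(
    segments: list[SegmentRecord],
    genome: GenomeModel,
    cfg: EventCallingConfig | None = None,
) -> list[GenomicEvent]:
    """Call genomic events from one sample's segmented profile.

    Events are returned sorted by (chromosome, arm, class, start) and the
    call is fully deterministic.
    """
    cfg = cfg or EventCallingConfig()
    if not segments:
        return []
    sample_id = segments[0].sample_id
    by_chrom = _validate_segments(segments, genome)
    events: list[GenomicEvent] = []

    for chrom, segs in sorted(by_chrom.items(), key=lambda kv: _chrom_key(kv[0])):
        chrom_len = genome.chromosomes[chrom].length
        runs = _merge_runs(segs, cfg.baseline_ploidy)

        # numerical whole-chromosome changes emit no SCA
        segmental_runs = []
        for run in runs:
            if run[2] - run[1] >= cfg.whole_chrom_fraction * chrom_len:
                logger.debug(
                    "%s: %s run %d-%d covers >= %.0f%% of chromosome %s; "
                    "numerical change, no SCA",
                    sample_id, run[0], run[1], run[2],
                    cfg.whole_chrom_fraction * 100, chrom,
                )
            else:
                segmental_runs.append(run)

        # arm-level SCAs from total aberrant length per (arm, direction)
        per_arm: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for run in segmental_runs:
            for arm, state, s, e in _split_at_arms(run, genome, chrom):
                per_arm.setdefault((arm, state), []).append((s, e))
        for (arm, state), frags in sorted(per_arm.items()):
            total = sum(e - s for s, e in frags)
            if total >= cfg.min_sca_size:
                events.append(
                    GenomicEvent(
                        sample_id=sample_id,
                        event_class=f"sca_{state}",
                        chrom=chrom,
                        start=min(s for s, _ in frags),
                        end=max(e for _, e in frags),
                        arm=arm,
                        direction=state,
                        n_breaks=len(frags),
                        catalog_label=genome.catalog_label(arm, state),
                    )
                )

        # focal aberrations over catalogue genes (TERT/ATRX); focal runs at
        # amplification level are amplifications, not FSCAs
        for state, s, e in segmental_runs:
            if e - s >= cfg.focal_max_size:
                continue
            if any(
                seg.start < e and s < seg.end
                and seg.total_cn >= cfg.amplification_cn
                for seg in segs
            ):
                continue
            hit = None
            for sym, (gchrom, gs, ge) in genome.gene_catalog.items():
                if sym in EXCLUDED_AMP_GENES:
                    continue
                if gchrom == chrom and s < ge and gs < e:
                    hit = sym
                    break
            if hit is None:
                logger.debug(
                    "%s: focal %s %s:%d-%d hits no catalogue gene; dropped",
                    sample_id, state, chrom, s, e,
                )
                continue
            arm = genome.arm_at(chrom, (s + e) // 2) or genome.arm_at(chrom, s)
            events.append(
                GenomicEvent(
                    sample_id=sample_id,
                    event_class="fsca",
                    chrom=chrom,
                    start=s,
                    end=e,
                    arm=arm,
                    direction=state,
                    gene=hit,
                )
            )

        # copy-neutral LOH: contiguous LOH runs at baseline copy number
        loh_runs: list[tuple[int, int]] = []
        for seg in segs:
            if seg.loh and seg.total_cn == cfg.baseline_ploidy:
                if loh_runs and loh_runs[-1][1] == seg.start:
                    loh_runs[-1] = (loh_runs[-1][0], seg.end)
                else:
                    loh_runs.append((seg.start, seg.end))
        for s, e in loh_runs:
            if e - s >= cfg.cnloh_min_size:
                mid_arm = genome.arm_at(chrom, (s + e) // 2)
                events.append(
                    GenomicEvent(
                        sample_id=sample_id,
                        event_class="cnloh",
                        chrom=chrom,
                        start=s,
                        end=e,
                        arm=mid_arm or genome.arm_at(chrom, s),
                    )
                )

        # chromothripsis-like pattern: oscillation among <= 3 CN states
        switches, states = _count_switches(segs, chrom_len, cfg.baseline_ploidy)
        if switches >= cfg.ctlp_min_switches and len(states) <= 3:
            s = min(seg.start for seg in segs)
            e = max(seg.end for seg in segs)
            arm_s = genome.arm_at(chrom, s)
            arm_e = genome.arm_at(chrom, max(s, e - 1))
            events.append(
                GenomicEvent(
                    sample_id=sample_id,
                    event_class="ctlp",
                    chrom=chrom,
                    start=s,
                    end=e,
                    arm=arm_s if arm_s == arm_e else None,
                    n_breaks=switches,
                )
            )

        # amplifications
        amp_runs: list[tuple[int, int]] = []
        for seg in segs:
            if seg.total_cn >= cfg.amplification_cn:
                if amp_runs and amp_runs[-1][1] == seg.start:
                    amp_runs[-1] = (amp_runs[-1][0], seg.end)
                else:
                    amp_runs.append((seg.start, seg.end))
        for s, e in amp_runs:
            gene = None
            for sym, (gchrom, gs, ge) in genome.gene_catalog.items():
                if gchrom == chrom and s < ge and gs < e:
                    gene = sym
                    break
            events.append(
                GenomicEvent(
                    sample_id=sample_id,
                    event_class="amplification",
                    chrom=chrom,
                    start=s,
                    end=e,
                    arm=genome.arm_at(chrom, (s + e) // 2) or genome.arm_at(chrom, s),
                    direction="gain",
                    gene=gene,
                    counted=gene not in EXCLUDED_AMP_GENES,
                )
            )

    events.sort(key=_event_key)
    return events


def _count_switches(
    segs: list[SegmentRecord], chrom_len: int, ploidy: int
) -> tuple[int, set[int]]:
    """Copy-number state switches along one chromosome's piecewise profile.

    Uncovered gaps (including chromosome ends) count as baseline state, so
    a lone aberrant segment contributes two switches (enter and leave).
    """
    profile: list[int] = []
    pos = 0
    for seg in segs:
        if seg.start > pos:
            profile.append(ploidy)
        profile.append(seg.total_cn)
        pos = seg.end
    if pos < chrom_len:
        profile.append(ploidy)
    switches = sum(1 for a, b in zip(profile, profile[1:]) if a != b)
    states = set(profile)
    return switches, states


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24}


def _chrom_key(chrom: str):
    return (_CHROM_ORDER.get(chrom, 99), chrom)


def _event_key(ev: GenomicEvent):
    return (
        _chrom_key(ev.chrom),
        ev.arm or "",
        EVENT_CLASSES.index(ev.event_class),
        ev.start,
        ev.end,
    )


def sca_count(events: list[GenomicEvent]) -> int:
    """Number of segmental chromosomal aberrations in one sample's events.

    Counts one per (arm, direction) SCA entry — an arm with both a gain and
    a loss counts twice, a multi-fragment arm counts once.  Focal events,
    cnLOH, chromothripsis-like patterns and amplifications are excluded.
    """
    return sum(1 for ev in events if ev.event_class in ("sca_gain", "sca_loss"))
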