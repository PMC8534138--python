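"""Cross-sample event matching and the intra-tumour-heterogeneity call.

Events called per sample are matched across all samples of a case (solid
tumour regions and/or liquid biopsies taken at the same time).  Matched
events form clusters keyed by (event class, chromosome, arm-or-gene,
direction); within a key, events from different samples merge into one
cluster when their intervals reciprocally overlap by at least the
configured fraction.  A cluster is *differing* when

* it is absent from at least one of the case's samples, or
* its members' corresponding breakpoints differ by more than the shift
  tolerance (a "shift" in the chromosome break position), or
* its members' fragment counts differ (additional chromosome breaks).

The case-level statistic is the percentage of differing clusters among
all clusters; a case is ITH when any cluster differs and high-ITH when
that percentage reaches the (inclusive) 50% threshold.  MYCN/ALK
amplification clusters are annotations only and never counted.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .events import GenomicEvent, sca_count
from .genome import EventCallingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "SampleProfile",
    "EventCluster",
    "CaseComparison",
    "match_case",
    "brute_force_match",
    "cohort_summary",
    "reciprocal_overlap",
]

SAMPLE_TYPES = ("T1", "T2", "T3", "LBp", "LBm")
MYCN_STATUSES = ("non-MNA", "MNA", "hetMNA")
SAMPLE_DESIGNS = ("T+T", "T+LB", "T+T+LB", "LB+LB")


@dataclass(frozen=True)
class SampleProfile:
    sample_id: str
    case_id: str
    sample_type: str
    events: tuple[GenomicEvent, ...]

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample_type must be one of {SAMPLE_TYPES}, got "
                f"{self.sample_type!r}"
            )
        for ev in self.events:
            if ev.sample_id != self.sample_id:
                raise ValueError(
                    f"event sample_id {ev.sample_id!r} != profile "
                    f"sample_id {self.sample_id!r}"
                )

    @property
    def is_liquid(self) -> bool:
        return self.sample_type.startswith("LB")


@dataclass
class EventCluster:
    key: tuple
    members: dict[str, GenomicEvent]  # sample_id -> event
    shift: bool = False
    extra_breaks: bool = False
    counted: bool = True

    @property
    def present_in(self) -> frozenset[str]:
        return frozenset(self.members)

    def interval(self) -> tuple[int, int]:
        return (
            min(ev.start for ev in self.members.values()),
            max(ev.end for ev in self.members.values()),
        )

    def differing(self, all_samples: frozenset[str]) -> bool:
        return (
            self.present_in != all_samples or self.shift or self.extra_breaks
        )


@dataclass
class CaseComparison:
    case_id: str
    mycn_status: str
    sample_ids: tuple[str, ...]
    sample_design: str
    clusters: list[EventCluster]
    n_total_events: int
    n_diff_events: int
    pct_diff: float | None  # None when n_total_events == 0
    ith: bool
    high_ith: bool | None  # None (not applicable) when not ITH
    sca_counts: dict[str, int] = field(default_factory=dict)
    sample_types: dict[str, str] = field(default_factory=dict)

    @property
    def lb_vs_t(self) -> str | None:
        """Direction of the solid-vs-liquid SCA-burden comparison."""
        lb = [n for s, n in self.sca_counts.items()
              if self.sample_types.get(s, "").startswith("LB")]
        t = [n for s, n in self.sca_counts.items()
             if self.sample_types.get(s, "T").startswith("T")]
        if not lb or not t:
            return None
        if max(lb) > max(t):
            return "more in LB"
        if max(t) > max(lb):
            return "more in T"
        return "equal"


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap length divided by the larger interval length (0 if disjoint)."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / max(a[1] - a[0], b[1] - b[0])


def _event_match_key(ev: GenomicEvent) -> tuple:
    anchor = ev.gene if ev.event_class in ("fsca", "amplification") and ev.gene else ev.arm
    return (ev.event_class, ev.chrom, anchor, ev.direction)


def cluster_intervals(
    items: list[tuple[str, int, int]], min_ro: float
) -> list[list[int]]:
    """Complete-linkage clustering of (sample, start, end) tuples.

    A valid cluster holds at most one interval per sample with every pair
    reciprocally overlapping >= ``min_ro``; among valid partitions the one
    maximizing the total pairwise reciprocal overlap is chosen (ties:
    fewest clusters, then smallest start order).  Small instances (the
    pipeline emits at most one event per sample under a given match key,
    so a key rarely holds more than a handful) are solved exactly by a
    pruned recursive assignment; larger inputs fall back to greedy
    agglomeration with single-move refinement.  Returns index groups into
    ``items``.
    """
    if len(items) <= 10:
        return _cluster_exact(items, min_ro)
    return _cluster_greedy(items, min_ro)


def _cluster_exact(
    items: list[tuple[str, int, int]], min_ro: float
) -> list[list[int]]:
    order = sorted(range(len(items)),
                   key=lambda i: (items[i][1], items[i][2], items[i][0]))

    def _ro(i: int, j: int) -> float:
        return reciprocal_overlap(items[i][1:], items[j][1:])

    best_score: tuple | None = None
    best_parts: list[list[int]] | None = None

    def assign(pos: int, parts: list[list[int]], total: float) -> None:
        nonlocal best_score, best_parts
        if pos == len(order):
            score = (total, -len(parts))
            if best_score is None or score > best_score:
                best_score = score
                best_parts = [list(cl) for cl in parts]
            return
        i = order[pos]
        for cl in parts:
            if items[i][0] in {items[j][0] for j in cl}:
                continue
            ros = [_ro(i, j) for j in cl]
            if min(ros) < min_ro:
                continue
            cl.append(i)
            assign(pos + 1, parts, total + sum(ros))
            cl.pop()
        parts.append([i])
        assign(pos + 1, parts, total)
        parts.pop()

    assign(0, [], 0.0)
    assert best_parts is not None
    return [sorted(cl) for cl in
            sorted(best_parts, key=lambda cl: min(items[i][1] for i in cl))]


def _cluster_greedy(
    items: list[tuple[str, int, int]], min_ro: float
) -> list[list[int]]:
    """Greedy agglomeration maximizing summed overlap, with refinement."""
    order = sorted(range(len(items)), key=lambda i: (items[i][1], items[i][2], items[i][0]))
    clusters: list[list[int]] = [[i] for i in order]

    def _ro(i: int, j: int) -> float:
        return reciprocal_overlap(items[i][1:], items[j][1:])

    while True:
        best = None
        best_pair = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                if {items[i][0] for i in ca} & {items[i][0] for i in cb}:
                    continue
                ros = [_ro(i, j) for i in ca for j in cb]
                if min(ros) < min_ro:
                    continue
                score = (
                    sum(ros),
                    min(ros),
                    -min(items[i][1] for i in ca + cb),
                )
                if best is None or score > best:
                    best, best_pair = score, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]

    # local refinement: move single members between clusters while the
    # summed overlap strictly improves (escapes greedy merge-order traps
    # when two aberration loci overlap ambiguously)
    improved = True
    while improved:
        improved = False
        for ci in range(len(clusters)):
            for i in list(clusters[ci]):
                current = [j for j in clusters[ci] if j != i]
                stay_gain = sum(_ro(i, j) for j in current)
                for cj in range(len(clusters)):
                    if cj == ci:
                        continue
                    target = clusters[cj]
                    if items[i][0] in {items[j][0] for j in target}:
                        continue
                    ros = [_ro(i, j) for j in target]
                    if min(ros) < min_ro:
                        continue
                    if sum(ros) > stay_gain + 1e-12:
                        clusters[ci] = current
                        clusters[cj] = sorted(target + [i])
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break
        clusters = [cl for cl in clusters if cl]
    return clusters


def _cluster_events(
    events: list[GenomicEvent], min_ro: float
) -> list[list[GenomicEvent]]:
    """Cluster same-key events across samples (see :func:`cluster_intervals`)."""
    items = [(e.sample_id, e.start, e.end) for e in events]
    return [[events[i] for i in group]
            for group in cluster_intervals(items, min_ro)]


def brute_force_match(
    events: list[GenomicEvent], min_ro: float
) -> list[list[GenomicEvent]]:
    """Exhaustive same-key matcher for small instances (oracle).

    Enumerates every partition of the events into clusters holding at most
    one event per sample with all pairs reciprocally overlapping >= min_ro,
    and returns the partition maximizing total pairwise overlap (ties:
    fewest clusters).  Exponential; intended for <= ~8 events.
    """
    events = sorted(events, key=lambda e: (e.start, e.end, e.sample_id))
    if len(events) > 10:
        raise ValueError("brute-force matcher limited to 10 events")

    best: tuple | None = None
    best_parts: list[list[GenomicEvent]] | None = None

    def valid(cluster: list[GenomicEvent]) -> bool:
        samples = [e.sample_id for e in cluster]
        if len(samples) != len(set(samples)):
            return False
        return all(
            reciprocal_overlap((a.start, a.end), (b.start, b.end)) >= min_ro
            for a, b in itertools.combinations(cluster, 2)
        )

    def score(parts: list[list[GenomicEvent]]) -> tuple:
        total = sum(
            reciprocal_overlap((a.start, a.end), (b.start, b.end))
            for cl in parts
            for a, b in itertools.combinations(cl, 2)
        )
        return (total, -len(parts))

    def partitions(items: list[GenomicEvent]):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for sub in partitions(rest):
            for i, cl in enumerate(sub):
                yield sub[:i] + [cl + [first]] + sub[i + 1:]
            yield sub + [[first]]

    for parts in partitions(events):
        if all(valid(cl) for cl in parts):
            sc = score(parts)
            if best is None or sc > best:
                best, best_parts = sc, parts
    assert best_parts is not None
    return [
        sorted(cl, key=lambda e: (e.start, e.end, e.sample_id))
        for cl in sorted(best_parts, key=lambda cl: min(e.start for e in cl))
    ]


def _breakpoint_shift(cluster: list[GenomicEvent], tol: int) -> bool:
    for a, b in itertools.combinations(cluster, 2):
        if abs(a.start - b.start) > tol or abs(a.end - b.end) > tol:
            return True
    return False


def match_case(
    profiles: list[SampleProfile],
    cfg: EventCallingConfig | None = None,
    mycn_status: str = "non-MNA",
) -> CaseComparison:
    """Match events across one case's samples and classify its ITH status."""
    cfg = cfg or EventCallingConfig()
    if not profiles:
        raise ValueError("empty profile list")
    case_ids = {p.case_id for p in profiles}
    if len(case_ids) > 1:
        raise ValueError(f"profiles from mixed cases: {sorted(case_ids)}")
    if mycn_status not in MYCN_STATUSES:
        raise ValueError(f"unknown MYCN status {mycn_status!r}")
    if len(profiles) == 1:
        warnings.warn(
            f"case {profiles[0].case_id}: single sample, ITH not assessable",
            stacklevel=2,
        )

    profiles = sorted(profiles, key=lambda p: p.sample_id)
    all_samples = frozenset(p.sample_id for p in profiles)

    by_key: dict[tuple, list[GenomicEvent]] = {}
    for p in profiles:
        for ev in p.events:
            by_key.setdefault(_event_match_key(ev), []).append(ev)

    clusters: list[EventCluster] = []
    for key in sorted(by_key, key=lambda k: tuple(str(x) for x in k)):
        for members in _cluster_events(by_key[key], cfg.reciprocal_overlap):
            counted = all(m.counted for m in members)
            cl = EventCluster(
                key=key,
                members={m.sample_id: m for m in members},
                counted=counted,
            )
            if len(members) >= 2:
                cl.shift = _breakpoint_shift(members, cfg.shift_tolerance)
                cl.extra_breaks = len({m.n_breaks for m in members}) > 1
            clusters.append(cl)

    counted_clusters = [cl for cl in clusters if cl.counted]
    n_total = len(counted_clusters)
    n_diff = (
        sum(cl.differing(all_samples) for cl in counted_clusters)
        if len(profiles) >= 2
        else 0
    )
    pct = 100.0 * n_diff / n_total if n_total else None
    ith = n_diff >= 1
    high_ith = (pct >= cfg.high_ith_threshold) if ith else None

    return CaseComparison(
        case_id=profiles[0].case_id,
        mycn_status=mycn_status,
        sample_ids=tuple(p.sample_id for p in profiles),
        sample_design=infer_design([p.sample_type for p in profiles]),
        clusters=clusters,
        n_total_events=n_total,
        n_diff_events=n_diff,
        pct_diff=pct,
        ith=ith,
        high_ith=high_ith,
        sca_counts={p.sample_id: sca_count(list(p.events)) for p in profiles},
        sample_types={p.sample_id: p.sample_type for p in profiles},
    )


def infer_design(sample_types: list[str]) -> str:
    """Collapse a case's sample types into the study's design categories."""
    n_t = sum(1 for t in sample_types if t.startswith("T"))
    n_lb = sum(1 for t in sample_types if t.startswith("LB"))
    if n_t >= 2 and n_lb >= 1:
        return "T+T+LB"
    if n_t >= 1 and n_lb >= 1:
        return "T+LB"
    if n_t >= 2:
        return "T+T"
    if n_lb >= 2:
        return "LB+LB"
    return "single"


def cohort_summary(comparisons: list[CaseComparison]) -> pd.DataFrame:
    """Per MYCN-status and per sample-design ITH summary.

    One row per (mycn_status, sample_design) group plus an ``all`` row;
    means/medians of total events, differing events and percent differing
    are taken over the group's ITH cases, mirroring the per-case table of
    heterogeneous cases.
    """
    if not comparisons:
        return pd.DataFrame(
            columns=[
                "mycn_status", "sample_design", "n_cases", "n_ith",
                "mean_total", "median_total", "mean_diff", "median_diff",
                "mean_pct_diff", "median_pct_diff",
                "more_in_lb", "more_in_t", "equal_burden",
            ]
        )

    rows = []
    groups: dict[tuple[str, str], list[CaseComparison]] = {}
    for cc in comparisons:
        groups.setdefault((cc.mycn_status, cc.sample_design), []).append(cc)
    for key in sorted(groups) + [("all", "all")]:
        ccs = groups.get(key, comparisons)
        ith_ccs = [cc for cc in ccs if cc.ith]
        tot = pd.Series([cc.n_total_events for cc in ith_ccs], dtype=float)
        dif = pd.Series([cc.n_diff_events for cc in ith_ccs], dtype=float)
        pct = pd.Series(
            [cc.pct_diff for cc in ith_ccs if cc.pct_diff is not None],
            dtype=float,
        )
        directions = [cc.lb_vs_t for cc in ith_ccs]
        rows.append(
            {
                "mycn_status": key[0],
                "sample_design": key[1],
                "n_cases": len(ccs),
                "n_ith": len(ith_ccs),
                "mean_total": tot.mean(),
                "median_total": tot.median(),
                "mean_diff": dif.mean(),
                "median_diff": dif.median(),
                "mean_pct_diff": pct.mean(),
                "median_pct_diff": pct.median(),
                "more_in_lb": directions.count("more in LB"),
                "more_in_t": directions.count("more in T"),
                "equal_burden": directions.count("equal"),
            }
        )
    return pd.DataFrame(rows)
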