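"""Synthetic multi-region + liquid-biopsy cohort generator.

Emulates the study design of a high-risk neuroblastoma spatial-ITH cohort:
each case draws a MYCN status (non-MNA / MNA / hetMNA), a sampling design
(two tumour regions, tumour + liquid biopsy, both, or two liquid
biopsies), a set of truncal segmental aberrations shared by all clones,
and per-region private subclones carrying additional aberrations at a
clonal fraction.  A liquid biopsy is a mixture of the tumour regions plus,
optionally, a metastatic-only clone, so each aberration reaches the ctDNA
at a mixture-weighted clonal fraction.  A single-threshold sensor then
censors every aberration whose effective clonal fraction falls below the
detection limit (~30%, the practical sensitivity of SNP-array calling),
which is what makes region-private and metastasis-private events appear
and disappear between samples.  Shared breakpoints receive small normal
jitter per sample; occasional cases carry a genuine breakpoint shift
(> the 5 Mb shift tolerance, still reciprocally overlapping) or an extra
chromosome break (one sample sees the aberration split in two fragments).
Survival times follow an exponential (optionally Weibull) model whose
progression hazard is multiplied for non-ITH cases, reproducing the
direction of the observed ITH survival advantage.

All randomness flows from a single seed, and the clonal structure is drawn
*before* the detection filter is applied, so changing the detection limit
re-censors the same cohort rather than generating a new one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import SegmentRecord
from .genome import GenomeModel, load_genome, parse_signed_arm
from .survival import SurvivalRecord

__all__ = ["SimConfig", "SimEvent", "CaseTruth", "SimTruth", "SimulatedCohort",
           "simulate_cohort", "default_arm_weights"]

# cohort composition of the emulated study: 58 cases, 32/20/6 MYCN groups,
# sampling designs 24 T+T / 21 T+LB / 11 T+T+LB / 2 LB+LB
_MYCN_PROBS = {"non-MNA": 32 / 58, "MNA": 20 / 58, "hetMNA": 6 / 58}
_DESIGN_PROBS = {"T+T": 24 / 58, "T+LB": 21 / 58, "T+T+LB": 11 / 58,
                 "LB+LB": 2 / 58}
_DESIGN_SAMPLES = {
    "T+T": ("T1", "T2"),
    "T+LB": ("T1", "LBp"),
    "T+T+LB": ("T1", "T2", "LBp"),
    "LB+LB": ("LBp", "LBm"),
}
# per-status mean SCA burden (truncal events per case), shaped by the
# reported group averages (non-MNA ~9-13, MNA ~5.4, hetMNA ~11.7)
_TRUNCAL_RATE = {"non-MNA": 9.0, "MNA": 5.0, "hetMNA": 11.0}


def default_arm_weights() -> dict[str, float]:
    """Sampling weights per signed arm, shaped by the reported per-group
    frequencies of typical and the most common atypical aberrations."""
    return {
        "+17q": 0.85, "11q-": 0.60, "1p-": 0.60, "3p-": 0.40, "+2p": 0.40,
        "+1q": 0.20, "4p-": 0.20,
        "+7q": 0.30, "+12q": 0.25, "14q-": 0.20, "+6p": 0.15, "6q-": 0.15,
        "9p-": 0.10, "19p-": 0.08, "21q-": 0.08,
        # occasional non-catalogue arms
        "5q-": 0.05, "+13q": 0.05, "8p-": 0.05, "+18q": 0.05,
    }


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters of the synthetic cohort.

    Rates are means of Poisson draws; fractions are clonal fractions in
    (0, 1]; sizes in bp; times in months.
    """

    n_cases: int = 58
    seed: int = 0
    mycn_probs: dict[str, float] = field(
        default_factory=lambda: dict(_MYCN_PROBS))
    design_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DESIGN_PROBS))
    truncal_rate: dict[str, float] = field(
        default_factory=lambda: dict(_TRUNCAL_RATE))
    ith_prone_prob: float = 0.35  # case is clonally diversifying
    private_rate: float = 2.0  # mean private events per region subclone
    # (private subclones and metastatic clones arise in prone cases only;
    # the two-class structure reproduces both the ~38% cohort ITH rate and
    # the heavy-tailed differing-event counts of heterogeneous cases)
    arm_weights: dict[str, float] = field(default_factory=default_arm_weights)
    subclone_fraction_range: tuple[float, float] = (0.15, 0.9)
    metastatic_prob: float = 0.5  # a prone case's LB carries a met-only clone
    jitter_sd: float = 1_000_000.0
    shift_prob: float = 0.08  # case carries a breakpoint shift
    extra_break_prob: float = 0.1  # case carries an extra-break split
    fsca_prob: float = 0.15  # non-MNA case carries a TERT/ATRX focal event
    detection_limit: float = 0.30
    # survival model
    progression_hazard: float = 0.02  # per month, ITH baseline
    post_progression_hazard: float = 0.06  # progression -> death
    nonith_hazard_multiplier: float = 2.5
    censor_window: tuple[float, float] = (24.0, 130.0)  # follow-up, uniform
    survival_dist: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.2
    # event geometry
    shift_tolerance: int = 5_000_000
    min_event_size: int = 3_000_000

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for name in ("mycn_probs", "design_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        lo, hi = self.subclone_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("subclone_fraction_range must lie in (0, 1]")
        if self.private_rate < 0 or min(self.truncal_rate.values()) < 0:
            raise ValueError("rates must be >= 0")
        if self.survival_dist not in ("exponential", "weibull"):
            raise ValueError("survival_dist must be exponential or weibull")


@dataclass
class SimEvent:
    """One simulated aberration with per-sample coordinates and fractions."""

    uid: int
    kind: str  # sca / fsca / mycn_amp
    chrom: str
    arm: str
    direction: str  # gain / loss
    cn: int
    base_start: int
    base_end: int
    clone: str  # "truncal", region id ("T1"...), or "met"
    fractions: dict[str, float]  # sample_id -> effective clonal fraction
    coords: dict[str, list[tuple[int, int]]]  # sample_id -> fragment list
    shifted: bool = False
    split_sample: str | None = None

    def detected_in(self, limit: float) -> frozenset[str]:
        return frozenset(s for s, f in self.fractions.items() if f >= limit)


@dataclass
class CaseTruth:
    case_id: str
    mycn_status: str
    design: str
    sample_ids: tuple[str, ...]
    events: list[SimEvent]
    ith: bool = False
    high_ith: bool | None = None
    n_total: int = 0
    n_diff: int = 0

    def recompute(
        self,
        detection_limit: float,
        shift_tolerance: float,
        min_reciprocal_overlap: float = 0.5,
        min_event_size: int = 3_000_000,
    ) -> None:
        """Derive the expected pipeline-level labels from the assignments.

        Works directly off each event's per-sample fragment coordinates: an
        occurrence is observable in a sample when its effective clonal
        fraction clears the detection limit and (for segmental events) its
        aberrant length clears the minimum segmental size after jitter.
        Observable occurrences are grouped with the same complete-linkage
        reciprocal-overlap rule the matcher uses; a group is differing when
        absent from some sample, when breakpoints differ beyond the shift
        tolerance, or when fragment counts differ.
        """
        from .heterogeneity import cluster_intervals

        all_s = frozenset(self.sample_ids)
        n_total = n_diff = 0
        for ev in self.events:
            det = sorted(ev.detected_in(detection_limit))
            if ev.kind == "sca":
                det = [
                    s for s in det
                    if sum(b - a for a, b in ev.coords[s]) >= min_event_size
                ]
            if not det or ev.kind == "mycn_amp":
                continue
            spans = {
                s: (min(a for a, _ in ev.coords[s]),
                    max(b for _, b in ev.coords[s]))
                for s in det
            }
            items = [(s, spans[s][0], spans[s][1]) for s in det]
            for group in cluster_intervals(items, min_reciprocal_overlap):
                members = [items[i][0] for i in group]
                n_total += 1
                if frozenset(members) != all_s:
                    n_diff += 1
                    continue
                shift = any(
                    abs(spans[a][0] - spans[b][0]) > shift_tolerance
                    or abs(spans[a][1] - spans[b][1]) > shift_tolerance
                    for i, a in enumerate(members)
                    for b in members[i + 1:]
                )
                extra = len({len(ev.coords[s]) for s in members}) > 1
                if shift or extra:
                    n_diff += 1
        self.n_total = n_total
        self.n_diff = n_diff
        self.ith = n_diff >= 1 and len(self.sample_ids) >= 2
        self.high_ith = (
            (100.0 * n_diff / n_total >= 50.0) if self.ith else None
        )


@dataclass
class SimTruth:
    cases: list[CaseTruth]

    @property
    def ith_fraction(self) -> float:
        return float(np.mean([c.ith for c in self.cases]))


@dataclass
class SimulatedCohort:
    """In-memory simulated cohort; writers live in :mod:`nbith.io`."""

    config: SimConfig
    segments: dict[str, list[SegmentRecord]]  # sample_id -> profile
    manifest: pd.DataFrame  # case_id, sample_id, sample_type, mycn_status
    survival: list[SurvivalRecord]
    truth: SimTruth


def _draw_interval(rng, arm, min_size: int) -> tuple[int, int]:
    max_len = int(arm.length * 0.9)
    lo = min(min_size * 2, max_len)
    length = int(rng.uniform(lo, max_len)) if max_len > lo else max_len
    start = int(rng.uniform(arm.start, arm.end - length))
    return start, start + length


def _clamp(s: int, e: int, arm) -> tuple[int, int]:
    s = max(arm.start, min(s, arm.end - 1))
    e = max(s + 1, min(e, arm.end))
    return s, e


def simulate_cohort(
    cfg: SimConfig, genome: GenomeModel | None = None
) -> SimulatedCohort:
    """Generate a full synthetic cohort from a single seed.

    Returns per-sample segmented profiles (only aberrant segments are
    written; everything else is baseline diploid), a case/sample manifest,
    a survival table, and the ground truth needed for recovery tests.
    """
    genome = genome or load_genome("default")
    rng = np.random.default_rng(cfg.seed)
    arm_labels = sorted(cfg.arm_weights)
    weights = np.array([cfg.arm_weights[a] for a in arm_labels], dtype=float)
    weights = weights / weights.sum()
    lo_f, hi_f = cfg.subclone_fraction_range

    segments: dict[str, list[SegmentRecord]] = {}
    manifest_rows = []
    survival: list[SurvivalRecord] = []
    truths: list[CaseTruth] = []
    uid = 0

    for i in range(cfg.n_cases):
        case_id = f"case{i + 1:03d}"
        status = str(rng.choice(list(cfg.mycn_probs), p=list(cfg.mycn_probs.values())))
        design = str(rng.choice(list(cfg.design_probs), p=list(cfg.design_probs.values())))
        sample_types = _DESIGN_SAMPLES[design]
        sample_ids = tuple(f"{case_id}_{t}" for t in sample_types)
        solid = [s for s, t in zip(sample_ids, sample_types) if t.startswith("T")]
        liquid = [s for s, t in zip(sample_ids, sample_types) if t.startswith("LB")]
        # latent tumour regions feeding the liquid biopsy: the sampled solid
        # regions, or two unsampled regions for pure liquid designs
        regions = solid if solid else ["R1", "R2"]

        # --- clonal structure -------------------------------------------
        events: list[SimEvent] = []
        used_arms: set[tuple[str, str]] = set()

        def draw_signed_arms(n: int) -> list[tuple[str, str]]:
            out = []
            for _ in range(n):
                for _attempt in range(20):
                    label = arm_labels[int(rng.choice(len(arm_labels), p=weights))]
                    arm, direction = parse_signed_arm(label)
                    if (arm, direction) not in used_arms:
                        used_arms.add((arm, direction))
                        out.append((arm, direction))
                        break
            return out

        n_truncal = int(rng.poisson(cfg.truncal_rate.get(status, 9.0)))
        truncal_arms = draw_signed_arms(n_truncal)

        # region subclones: fraction + private events in clonally
        # diversifying (ITH-prone) cases; hetMNA cases showed no
        # array-level SCA heterogeneity and stay truncal-only
        prone = rng.uniform() < cfg.ith_prone_prob and status != "hetMNA"
        private: dict[str, list[tuple[str, str]]] = {}
        subclone_frac: dict[str, float] = {}
        for r in regions:
            subclone_frac[r] = float(rng.uniform(lo_f, hi_f))
            n_priv = int(rng.poisson(cfg.private_rate)) if prone else 0
            private[r] = draw_signed_arms(n_priv)
        met_frac = float(rng.uniform(lo_f, hi_f))
        has_met = bool(liquid) and prone and rng.uniform() < cfg.metastatic_prob
        n_met = int(rng.poisson(cfg.private_rate))
        met_arms = draw_signed_arms(n_met) if has_met else []

        # liquid-biopsy mixture weights over regions (Dirichlet), one draw
        # per liquid sample; medullary aspirates weigh the metastatic clone
        lb_weights: dict[str, np.ndarray] = {}
        lb_met_frac: dict[str, float] = {}
        for s, t in zip(sample_ids, sample_types):
            if t.startswith("LB"):
                lb_weights[s] = rng.dirichlet(np.ones(len(regions)))
                boost = 1.0 if t == "LBm" else 0.6
                lb_met_frac[s] = met_frac * boost if has_met else 0.0

        def effective_fractions(clone: str) -> dict[str, float]:
            fr: dict[str, float] = {}
            for s, t in zip(sample_ids, sample_types):
                if t.startswith("T"):
                    if clone == "truncal":
                        fr[s] = 1.0
                    elif clone == s:
                        fr[s] = subclone_frac[s]
                    else:
                        fr[s] = 0.0
                else:
                    if clone == "truncal":
                        fr[s] = 1.0
                    elif clone == "met":
                        fr[s] = lb_met_frac[s]
                    elif clone in regions:
                        w = lb_weights[s][regions.index(clone)]
                        fr[s] = float(w * subclone_frac[clone])
                    else:
                        fr[s] = 0.0
            return fr

        def add_event(kind, arm_name, direction, clone, cn=None,
                      interval=None) -> SimEvent:
            nonlocal uid
            arm = genome.arms[arm_name]
            if interval is None:
                interval = _draw_interval(rng, arm, cfg.min_event_size)
                if kind == "sca" and status == "MNA" and arm_name == "2p" \
                        and direction == "gain":
                    # 2p gains in MYCN-amplified tumours span the MYCN locus
                    # (proximal 2p24), with margin for breakpoint jitter
                    gs = genome.gene_catalog["MYCN"][1]
                    ge = genome.gene_catalog["MYCN"][2]
                    interval = (
                        min(interval[0], max(arm.start, gs - 6_500_000)),
                        max(interval[1], min(arm.end, ge + 6_500_000)),
                    )
            # per-sample breakpoint jitter, drawn for every sample up front
            coords = {}
            for s in sample_ids:
                ds, de = rng.normal(0, cfg.jitter_sd, size=2)
                coords[s] = [_clamp(int(interval[0] + ds),
                                    int(interval[1] + de), arm)]
            ev = SimEvent(
                uid=uid, kind=kind, chrom=arm.chrom, arm=arm_name,
                direction=direction,
                cn=cn if cn is not None else (3 if direction == "gain" else 1),
                base_start=interval[0], base_end=interval[1], clone=clone,
                fractions=effective_fractions(clone), coords=coords,
            )
            uid += 1
            events.append(ev)
            return ev

        for arm_name, direction in truncal_arms:
            add_event("sca", arm_name, direction, "truncal")
        for r in regions:
            for arm_name, direction in private[r]:
                add_event("sca", arm_name, direction, r)
        for arm_name, direction in met_arms:
            add_event("sca", arm_name, direction, "met")

        # focal TERT/ATRX aberration (non-MNA cases only)
        if status == "non-MNA" and rng.uniform() < cfg.fsca_prob:
            gene = "TERT" if rng.uniform() < 0.5 else "ATRX"
            gchrom, gs, ge = genome.gene_catalog[gene]
            direction = "gain" if gene == "TERT" else "loss"
            length = int(rng.uniform(400_000, 2_500_000))
            start = max(0, gs - int(rng.uniform(0, length // 2)))
            clone = "truncal" if rng.uniform() < 0.5 else regions[
                int(rng.choice(len(regions)))]
            arm_name = genome.arm_at(gchrom, gs)
            ev = add_event("fsca", arm_name, direction, clone,
                           interval=(start, start + length))
            ev.coords = {s: [(start, start + length)] for s in sample_ids}

        # MYCN amplification is truncal in MNA cases (annotation-only in
        # hetMNA) and never counted as a genomic event downstream
        if status == "MNA":
            gchrom, gs, ge = genome.gene_catalog["MYCN"]
            arm_name = genome.arm_at(gchrom, gs)
            ev = add_event("mycn_amp", arm_name, "gain", "truncal", cn=30,
                           interval=(gs - 200_000, ge + 200_000))
            ev.coords = {s: [(gs - 200_000, ge + 200_000)] for s in sample_ids}

        # breakpoint shift: move one long shared event in one sample beyond
        # the shift tolerance while keeping reciprocal overlap >= ~0.55
        do_shift = rng.uniform() < cfg.shift_prob
        do_split = rng.uniform() < cfg.extra_break_prob
        shift_d = rng.uniform(1.2, 2.5)
        pick = rng.uniform(size=4)
        if do_shift and len(sample_ids) >= 2:
            long_ev = [e for e in events
                       if e.kind == "sca" and e.clone == "truncal"
                       and e.base_end - e.base_start >= 2.5 * cfg.shift_tolerance]
            if long_ev:
                ev = long_ev[int(pick[0] * len(long_ev))]
                s = sample_ids[int(pick[1] * len(sample_ids))]
                arm = genome.arms[ev.arm]
                length = ev.base_end - ev.base_start
                d = int(min(shift_d * cfg.shift_tolerance, 0.45 * length))
                sign = 1 if ev.base_end + d <= arm.end else -1
                (cs, ce), = ev.coords[s]
                ev.coords[s] = [_clamp(cs + sign * d, ce + sign * d, arm)]
                ev.shifted = True
        if do_split and len(sample_ids) >= 2:
            splittable = [e for e in events
                          if e.kind == "sca" and e.clone == "truncal"
                          and e.base_end - e.base_start >= 3 * cfg.min_event_size
                          and not e.shifted]
            if splittable:
                ev = splittable[int(pick[2] * len(splittable))]
                s = sample_ids[int(pick[3] * len(sample_ids))]
                (cs, ce), = ev.coords[s]
                mid = (cs + ce) // 2
                gap = 500_000
                ev.coords[s] = [(cs, mid - gap), (mid + gap, ce)]
                ev.split_sample = s

        truth = CaseTruth(case_id, status, design, sample_ids, events)
        truth.recompute(cfg.detection_limit, cfg.shift_tolerance,
                        min_event_size=cfg.min_event_size)
        truths.append(truth)

        # --- survival ---------------------------------------------------
        mult = 1.0 if truth.ith else cfg.nonith_hazard_multiplier
        u1, u2 = rng.uniform(size=2)
        if cfg.survival_dist == "exponential":
            t_prog = -np.log(u1) / (cfg.progression_hazard * mult)
        else:
            scale = 1.0 / (cfg.progression_hazard * mult)
            t_prog = scale * (-np.log(u1)) ** (1.0 / cfg.weibull_shape)
        t_death = t_prog - np.log(u2) / cfg.post_progression_hazard
        follow = rng.uniform(*cfg.censor_window)
        survival.append(
            SurvivalRecord(
                case_id=case_id,
                efs_months=round(min(t_prog, follow), 1),
                efs_event=t_prog <= follow,
                os_months=round(min(t_death, follow), 1),
                os_event=t_death <= follow,
            )
        )

        # --- materialize segment profiles (pure detection filter) -------
        for s, t in zip(sample_ids, sample_types):
            segments[s] = _compose_profile(
                s, [e for e in events
                    if e.fractions[s] >= cfg.detection_limit], genome)
            manifest_rows.append(
                {"case_id": case_id, "sample_id": s, "sample_type": t,
                 "mycn_status": status})

    manifest = pd.DataFrame(
        manifest_rows,
        columns=["case_id", "sample_id", "sample_type", "mycn_status"],
    )
    return SimulatedCohort(cfg, segments, manifest, survival, SimTruth(truths))


def _compose_profile(
    sample_id: str, detected: list[SimEvent], genome: GenomeModel
) -> list[SegmentRecord]:
    """Piecewise-constant copy-number profile from overlapping aberrations.

    Copy-number deltas of overlapping events add on top of the diploid
    baseline (e.g. a 2p gain containing a MYCN amplification); only
    non-baseline segments are emitted.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for ev in detected:
        for (s, e) in ev.coords[sample_id]:
            by_chrom.setdefault(ev.chrom, []).append((s, e, ev.cn - 2))
    out: list[SegmentRecord] = []
    for chrom in sorted(by_chrom):
        triples = by_chrom[chrom]
        points = sorted({p for s, e, _ in triples for p in (s, e)})
        for a, b in zip(points, points[1:]):
            delta = sum(d for s, e, d in triples if s <= a and b <= e)
            if delta != 0:
                out.append(
                    SegmentRecord(
                        sample_id=sample_id, chrom=chrom, start=a, end=b,
                        total_cn=max(0, 2 + delta),
                    )
                )
    return out


def simulate_replicates(cfg: SimConfig, n_replicates: int):
    """Yield independent cohorts with seeds derived from ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    for child in ss.spawn(n_replicates):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        yield simulate_cohort(replace(cfg, seed=child_seed))
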