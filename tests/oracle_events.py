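"""Per-base brute-force re-derivation of segmental event calls.

Labels every base of a mini chromosome gain/loss/neutral from the raw
segments, then re-derives maximal aberration runs, the whole-chromosome
(numerical) rule, per-arm fragment counts and totals, amplification runs
and the oscillation count — entirely independently of the interval
arithmetic in the event caller.
"""

from __future__ import annotations

import numpy as np

from nbith.events import SegmentRecord
from nbith.genome import EventCallingConfig, GenomeModel


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean per-base mask as (start, end)."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def per_base_calls(
    segments: list[SegmentRecord],
    genome: GenomeModel,
    cfg: EventCallingConfig,
) -> set[tuple]:
    """Expected (class, chrom, arm, start, end, n_breaks) call set.

    Covers sca_gain/sca_loss, amplification (arm of the run midpoint) and
    ctlp; focal/cnLOH semantics are exercised by dedicated unit tests.
    """
    calls: set[tuple] = set()
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)

    for chrom, segs in by_chrom.items():
        n = genome.chromosomes[chrom].length
        cn = np.full(n, cfg.baseline_ploidy, dtype=np.int16)
        for s in segs:
            cn[s.start:s.end] = s.total_cn

        # numerical-change rule: a maximal same-state aberrant run covering
        # >= whole_chrom_fraction of the chromosome emits nothing
        aberrant = {}
        for state, mask in (("gain", cn > cfg.baseline_ploidy),
                            ("loss", cn < cfg.baseline_ploidy)):
            keep = np.zeros(n, dtype=bool)
            for a, b in _runs(mask):
                if b - a < cfg.whole_chrom_fraction * n:
                    keep[a:b] = True
            aberrant[state] = keep

        for state in ("gain", "loss"):
            for arm in genome.chrom_arms(chrom):
                arm_mask = aberrant[state][arm.start:arm.end]
                total = int(arm_mask.sum())
                if total >= cfg.min_sca_size:
                    frags = _runs(arm_mask)
                    calls.add((
                        f"sca_{state}", chrom, arm.name,
                        arm.start + frags[0][0], arm.start + frags[-1][1],
                        len(frags),
                    ))

        amp_mask = cn >= cfg.amplification_cn
        for a, b in _runs(amp_mask):
            mid_arm = genome.arm_at(chrom, (a + b) // 2) or genome.arm_at(chrom, a)
            calls.add(("amplification", chrom, mid_arm, a, b, 1))

        switches = int(np.count_nonzero(np.diff(cn)))
        states = np.unique(cn)
        if switches >= cfg.ctlp_min_switches and len(states) <= 3:
            covered = np.zeros(n, dtype=bool)
            for s in segs:
                covered[s.start:s.end] = True
            runs = _runs(covered)
            a, b = runs[0][0], runs[-1][1]
            arm_a = genome.arm_at(chrom, a)
            arm_b = genome.arm_at(chrom, max(a, b - 1))
            calls.add(("ctlp", chrom, arm_a if arm_a == arm_b else None,
                       a, b, switches))
    return calls


def observed_calls(events) -> set[tuple]:
    """Project caller output onto the oracle's comparison tuple."""
    return {
        (e.event_class, e.chrom, e.arm, e.start, e.end,
         1 if e.event_class == "amplification" else e.n_breaks)
        for e in events
        if e.event_class in ("sca_gain", "sca_loss", "amplification", "ctlp")
    }


def random_mini_segments(rng, genome: GenomeModel, sample="s1") -> list[SegmentRecord]:
    """Random non-overlapping integer-CN segments on every mini chromosome."""
    segs = []
    for chrom in genome.chromosomes.values():
        n_seg = int(rng.integers(0, 9))
        if n_seg == 0:
            continue
        cuts = np.sort(rng.choice(chrom.length, size=2 * n_seg, replace=False))
        for i in range(n_seg):
            a, b = int(cuts[2 * i]), int(cuts[2 * i + 1])
            if a == b:
                continue
            cn = int(rng.choice([0, 1, 1, 2, 3, 3, 4, 8, 9],
                                p=[.04, .18, .18, .1, .18, .18, .06, .04, .04]))
            segs.append(SegmentRecord(sample, chrom.name, a, b, cn,
                                      loh=bool(rng.uniform() < 0.1)))
    return segs
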