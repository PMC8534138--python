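"""End-to-end driver: segments + manifest -> per-case ITH comparisons."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .events import SegmentRecord, extract_events
from .genome import EventCallingConfig, GenomeModel, load_genome
from .heterogeneity import CaseComparison, SampleProfile, match_case

__all__ = ["profiles_from_segments", "compare_cohort"]


def profiles_from_segments(
    segments: dict[str, list[SegmentRecord]],
    manifest: pd.DataFrame,
    genome: GenomeModel | None = None,
    cfg: EventCallingConfig | None = None,
) -> dict[str, list[SampleProfile]]:
    """Call events for every manifest sample, grouped per case.

    Samples listed in the manifest but absent from the segment collection
    are treated as aberration-free profiles (an empty SEG section), so a
    sample with no detectable aberrations still participates in matching.
    """
    genome = genome or load_genome("default")
    cfg = cfg or EventCallingConfig()
    by_case: dict[str, list[SampleProfile]] = {}
    for row in manifest.itertuples(index=False):
        segs = segments.get(row.sample_id, [])
        events = extract_events(segs, genome, cfg) if segs else []
        by_case.setdefault(str(row.case_id), []).append(
            SampleProfile(
                sample_id=str(row.sample_id),
                case_id=str(row.case_id),
                sample_type=str(row.sample_type),
                events=tuple(events),
            )
        )
    return by_case


def compare_cohort(
    segments: dict[str, list[SegmentRecord]],
    manifest: pd.DataFrame,
    genome: GenomeModel | None = None,
    cfg: EventCallingConfig | None = None,
) -> list[CaseComparison]:
    """Run event calling and cross-sample matching for every case."""
    cfg = cfg or EventCallingConfig()
    status = {
        str(r.case_id): str(r.mycn_status)
        for r in manifest.itertuples(index=False)
    }
    by_case = profiles_from_segments(segments, manifest, genome, cfg)
    return [
        match_case(profiles, cfg, mycn_status=status[case_id])
        for case_id, profiles in sorted(by_case.items())
    ]
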