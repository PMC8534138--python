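"""File formats, the packaged per-case fixture, and pipeline drivers.

Segmented profiles travel as SEG-style tab-separated text (1-based,
inclusive coordinates; converted to the internal 0-based half-open
convention on read), manifests and survival tables as comma- or
tab-separated text with headers.  The packaged fixture transcribes the
per-case table of the 22 heterogeneous cases of the emulated study
(case ids 1-14 non-MNA, 33-40 MNA): total and differing genomic events,
percent differing, and EFS/OS follow-up, which is the desk-scale surface
the survival statistics are checked against.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .events import SegmentRecord
from .heterogeneity import CaseComparison, cohort_summary
from .simulate import SimulatedCohort
from .survival import (
    SurvivalRecord,
    km_estimate,
    logrank,
    survival_at,
)

__all__ = [
    "read_segments",
    "write_segments",
    "read_manifest",
    "write_manifest",
    "read_survival",
    "write_survival",
    "write_truth",
    "write_cohort",
    "load_table2",
    "reproduce_table2",
    "comparison_table",
    "round_half_up",
]

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of the printed tables)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot parse boolean field {value!r}")


def _norm_chrom(chrom: str) -> str:
    return str(chrom).removeprefix("chr")


def read_segments(path: str | Path) -> dict[str, list[SegmentRecord]]:
    """Read a SEG-style file into per-sample segment lists.

    Expected header columns: sample, chrom, start, end, [num_mark], cn,
    [loh] (case-insensitive; ``ID``/``chromosome``/``loc.start`` synonyms
    accepted).  Input coordinates are 1-based inclusive; records are
    converted to 0-based half-open and validated (per-sample,
    per-chromosome non-overlap).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower().replace(".", "_"): c for c in df.columns}

    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    c_sample = col("sample", "sample_id", "id")
    c_chrom = col("chrom", "chromosome", "chr")
    c_start = col("start", "loc_start")
    c_end = col("end", "loc_end")
    c_cn = col("cn", "total_cn", "copy_number")
    c_loh = col("loh")
    missing = [n for n, c in
               [("sample", c_sample), ("chrom", c_chrom), ("start", c_start),
                ("end", c_end), ("cn", c_cn)] if c is None]
    if missing:
        raise ValueError(f"{path}: missing SEG columns {missing}")

    out: dict[str, list[SegmentRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            rec = SegmentRecord(
                sample_id=str(row[c_sample]),
                chrom=_norm_chrom(row[c_chrom]),
                start=int(row[c_start]) - 1,  # 1-based inclusive -> half-open
                end=int(row[c_end]),
                total_cn=int(row[c_cn]),
                loh=_parse_bool(row[c_loh]) if c_loh and not pd.isna(row[c_loh]) else False,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{i}: malformed segment line: {exc}") from exc
        out.setdefault(rec.sample_id, []).append(rec)

    for sample, segs in out.items():
        segs.sort(key=lambda s: (s.chrom, s.start))
        per_chrom: dict[str, SegmentRecord] = {}
        for seg in segs:
            prev = per_chrom.get(seg.chrom)
            if prev is not None and seg.start < prev.end:
                raise ValueError(
                    f"{path}: sample {sample} chromosome {seg.chrom}: "
                    f"overlapping segments {prev.start + 1}-{prev.end} and "
                    f"{seg.start + 1}-{seg.end}"
                )
            per_chrom[seg.chrom] = seg
    return out


def write_segments(
    segments: dict[str, list[SegmentRecord]], path: str | Path
) -> None:
    """Write per-sample segments as SEG (1-based inclusive, tab-separated)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tcn\tloh\n")
        for sample in sorted(segments):
            for seg in sorted(segments[sample], key=lambda s: (_chrom_sort(s.chrom), s.start)):
                fh.write(
                    f"{sample}\t{seg.chrom}\t{seg.start + 1}\t{seg.end}\t"
                    f"{seg.total_cn}\t{'yes' if seg.loh else 'no'}\n"
                )


def write_events(events, path: str | Path) -> None:
    """Write called events as BED-like TSV (0-based half-open intervals)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsample\tevent_class\tarm\tgene\t"
                 "n_breaks\tcatalog_label\tcounted\n")
        for ev in events:
            fh.write(
                f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.sample_id}\t"
                f"{ev.event_class}\t{ev.arm or '.'}\t{ev.gene or '.'}\t"
                f"{ev.n_breaks}\t{ev.catalog_label}\t"
                f"{'yes' if ev.counted else 'no'}\n"
            )


def _chrom_sort(chrom: str):
    order = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24}
    return (order.get(chrom, 99), chrom)


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    required = ["case_id", "sample_id", "sample_type", "mycn_status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return df[required]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = _read_table(path)
    required = ["case_id", "efs_months", "efs_event", "os_months", "os_event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: survival table missing columns {missing}")
    return [
        SurvivalRecord(
            case_id=str(r.case_id),
            efs_months=float(r.efs_months),
            efs_event=_parse_bool(r.efs_event),
            os_months=float(r.os_months),
            os_event=_parse_bool(r.os_event),
        )
        for r in df.itertuples(index=False)
    ]


def write_survival(records: list[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("case_id\tefs_months\tefs_event\tos_months\tos_event\n")
        for r in records:
            fh.write(
                f"{r.case_id}\t{r.efs_months:g}\t{'yes' if r.efs_event else 'no'}\t"
                f"{r.os_months:g}\t{'yes' if r.os_event else 'no'}\n"
            )


def write_truth(cohort: SimulatedCohort, path: str | Path) -> None:
    """Ground-truth labels, one record per case (tab-separated)."""
    with open(path, "w") as fh:
        fh.write("case_id\tmycn_status\tdesign\tn_samples\tn_total\tn_diff\t"
                 "ith\thigh_ith\n")
        for c in cohort.truth.cases:
            hi = "NA" if c.high_ith is None else ("yes" if c.high_ith else "no")
            fh.write(
                f"{c.case_id}\t{c.mycn_status}\t{c.design}\t"
                f"{len(c.sample_ids)}\t{c.n_total}\t{c.n_diff}\t"
                f"{'yes' if c.ith else 'no'}\t{hi}\n"
            )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write segments/manifest/survival/truth of a simulated cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": outdir / "segments.seg",
        "manifest": outdir / "manifest.tsv",
        "survival": outdir / "survival.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_segments(cohort.segments, paths["segments"])
    write_manifest(cohort.manifest, paths["manifest"])
    write_survival(cohort.survival, paths["survival"])
    write_truth(cohort, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# packaged per-case fixture (22 heterogeneous cases)

@dataclass(frozen=True)
class Table2Row:
    case_id: str
    mycn_status: str
    n_total_events: int
    n_diff_events: int
    pct_diff: float
    efs_months: float
    efs_event: bool
    os_months: float
    os_event: bool

    @property
    def high_ith(self) -> bool:
        return self.pct_diff >= 50.0

    @property
    def survival(self) -> SurvivalRecord:
        return SurvivalRecord(
            self.case_id, self.efs_months, self.efs_event,
            self.os_months, self.os_event,
        )


def load_table2() -> list[Table2Row]:
    """Load the packaged 22-case fixture, checking internal consistency.

    The printed percent-differing column must equal 100 * n_diff / n_total
    half-up rounded to two decimals for every row, and the high-ITH flag is
    the inclusive >= 50% rule.
    """
    text = (resources.files("nbith") / "data" / "table2.tsv").read_text()
    df = pd.read_csv(pd.io.common.StringIO(text), sep="\t", dtype=str)
    rows = []
    for r in df.itertuples(index=False):
        row = Table2Row(
            case_id=str(r.case_id),
            mycn_status=r.mycn_status,
            n_total_events=int(r.n_total_events),
            n_diff_events=int(r.n_diff_events),
            pct_diff=float(r.pct_diff),
            efs_months=float(r.efs_months),
            efs_event=_parse_bool(r.efs_event),
            os_months=float(r.os_months),
            os_event=_parse_bool(r.os_event),
        )
        recomputed = round_half_up(
            100.0 * row.n_diff_events / row.n_total_events
        )
        if recomputed != row.pct_diff:
            raise ValueError(
                f"fixture case {row.case_id}: pct {row.pct_diff} != "
                f"recomputed {recomputed}"
            )
        if row.efs_months > row.os_months:
            raise ValueError(f"fixture case {row.case_id}: EFS > OS")
        rows.append(row)
    if len(rows) != 22:
        raise ValueError(f"fixture must hold 22 cases, found {len(rows)}")
    return rows


def reproduce_table2(outdir: str | Path | None = None) -> dict:
    """Recompute the fixture-backed summary and survival statistics.

    Returns a report dict with the cohort means/medians, the high/low-ITH
    split, product-limit survival at 36/48/60 months per group and the
    Mantel-Cox comparisons; optionally writes tab-separated tables plus a
    human-readable summary under ``outdir``.
    """
    rows = load_table2()
    tot = np.array([r.n_total_events for r in rows], float)
    dif = np.array([r.n_diff_events for r in rows], float)
    pct = np.array([r.pct_diff for r in rows], float)
    efs = np.array([r.efs_months for r in rows], float)
    osm = np.array([r.os_months for r in rows], float)

    high = [r for r in rows if r.high_ith]
    low = [r for r in rows if not r.high_ith]
    high_surv = [r.survival for r in high]
    low_surv = [r.survival for r in low]
    non_mna = [r for r in rows if r.mycn_status == "non-MNA"]

    report: dict = {
        "n_cases": len(rows),
        "mean_total": round_half_up(float(tot.mean())),
        "median_total": float(np.median(tot)),
        "mean_diff": round_half_up(float(dif.mean())),
        "median_diff": float(np.median(dif)),
        "mean_pct_diff": round_half_up(float(pct.mean())),
        "median_pct_diff": round_half_up(float(np.median(pct))),
        "mean_efs_months": round_half_up(float(efs.mean())),
        "mean_os_months": round_half_up(float(osm.mean())),
        "n_high_ith": len(high),
        "n_low_ith": len(low),
        "mean_pct_diff_non_mna": round_half_up(
            float(np.mean([r.pct_diff for r in non_mna]))),
    }
    for label, group in [("high_ith", high_surv), ("low_ith", low_surv)]:
        for endpoint in ("efs", "os"):
            curve = km_estimate(group, endpoint)
            for t in (36, 48, 60):
                report[f"{label}_{endpoint}_s{t}"] = survival_at(curve, t)
    for endpoint in ("efs", "os"):
        res = logrank(high_surv, low_surv, endpoint)
        report[f"logrank_{endpoint}_chi2"] = res.chi2
        report[f"logrank_{endpoint}_p"] = res.p_value

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([vars(r) for r in rows]).to_csv(
            outdir / "table2_fixture.tsv", sep="\t", index=False)
        with open(outdir / "table2_report.txt", "w") as fh:
            for k, v in report.items():
                fh.write(f"{k}\t{v}\n")
    return report


def comparison_table(comparisons: list[CaseComparison]) -> pd.DataFrame:
    """Per-case comparison rows mirroring the fixture's columns plus flags."""
    rows = []
    for cc in comparisons:
        rows.append(
            {
                "case_id": cc.case_id,
                "mycn_status": cc.mycn_status,
                "sample_design": cc.sample_design,
                "n_samples": len(cc.sample_ids),
                "n_total_events": cc.n_total_events,
                "n_diff_events": cc.n_diff_events,
                "pct_diff": (
                    round_half_up(cc.pct_diff) if cc.pct_diff is not None else None
                ),
                "ith": cc.ith,
                "high_ith": cc.high_ith,
                "lb_vs_t": cc.lb_vs_t,
            }
        )
    return pd.DataFrame(rows)


def event_matrix(comparisons: list[CaseComparison]) -> pd.DataFrame:
    """Cases x signed-arm presence matrix (union over samples) as 0/1."""
    arms: set[str] = set()
    per_case: dict[str, set[str]] = {}
    for cc in comparisons:
        present = set()
        for cl in cc.clusters:
            if not cl.counted:
                continue
            ev = next(iter(cl.members.values()))
            if ev.signed_arm and ev.event_class.startswith("sca"):
                present.add(ev.signed_arm)
        arms |= present
        per_case[cc.case_id] = present
    cols = sorted(arms)
    data = [[int(a in per_case[c]) for a in cols] for c in per_case]
    return pd.DataFrame(data, index=list(per_case), columns=cols)
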