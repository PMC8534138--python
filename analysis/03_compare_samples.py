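#!/usr/bin/env python
"""Match events across each case's samples and classify ITH.

Produces the per-case comparison table (total events, differing events,
percent differing, ITH / high-ITH calls), the per-group cohort summary,
and the cases-by-arm event matrix.
"""

import argparse
from pathlib import Path

from nbith.heterogeneity import cohort_summary
from nbith.io import comparison_table, event_matrix, read_manifest, read_segments
from nbith.pipeline import compare_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--segments", type=Path,
                    default=Path("results/cohort/segments.seg"))
    ap.add_argument("--manifest", type=Path,
                    default=Path("results/cohort/manifest.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    segments = read_segments(args.segments)
    manifest = read_manifest(args.manifest)
    comparisons = compare_cohort(segments, manifest)

    args.outdir.mkdir(parents=True, exist_ok=True)
    table = comparison_table(comparisons)
    table.to_csv(args.outdir / "case_comparisons.tsv", sep="\t", index=False)
    summary = cohort_summary(comparisons)
    summary.to_csv(args.outdir / "cohort_summary.tsv", sep="\t",
                   index=False, float_format="%.2f")
    event_matrix(comparisons).to_csv(args.outdir / "event_matrix.tsv", sep="\t")

    n = len(comparisons)
    n_ith = int(table.ith.sum())
    n_high = int((table.high_ith == True).sum())  # noqa: E712 (None-aware)
    ith = table[table.ith]
    print(f"{n_ith}/{n} cases with ITH ({100 * n_ith / n:.1f}%); "
          f"{n_high} high-ITH (>= 50% differing events)")
    if not ith.empty:
        print(f"among ITH cases: mean {ith.n_diff_events.mean():.2f} "
              f"differing events, mean {ith.pct_diff.mean():.1f}% differing")
    print(f"  wrote {args.outdir / 'case_comparisons.tsv'}")
    print(f"  wrote {args.outdir / 'cohort_summary.tsv'}")
    print(f"  wrote {args.outdir / 'event_matrix.tsv'}")


if __name__ == "__main__":
    main()
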