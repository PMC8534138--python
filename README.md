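# nbith — spatial intra-tumour heterogeneity from multi-sample copy-number profiles

`nbith` quantifies **spatial intra-tumour heterogeneity (ITH)** in high-risk
neuroblastoma from segmented copy-number profiles of several samples taken
from the same patient at the same time — multiple solid tumour regions
(T1, T2, T3) and/or circulating tumour DNA from liquid biopsies of
peripheral blood (LBp) or bone-marrow aspirate (LBm). It is written for
analysts working with SNP-array or sequencing-derived segment calls who
want a reproducible, testable version of the event-level ITH statistic and
its survival analysis.

## The statistic

Each sample's segmented profile is reduced to **genomic events**:

- **SCA** (segmental chromosomal aberration): gain or loss of part of a
  chromosome arm, called per arm and direction when the aberrant length is
  ≥ 3 Mb, excluding numerical whole-chromosome changes (≥ 95% of the
  chromosome);
- **FSCA**: focal aberration < 3 Mb over the *TERT* or *ATRX* locus;
- **cnLOH**: copy-neutral loss of heterozygosity ≥ 10 Mb;
- **CTLP**: chromothripsis-like pattern (≥ 10 copy-number switches among
  ≤ 3 states on one chromosome);
- **amplification**: total copy number ≥ 8; *MYCN*/*ALK* amplification is
  annotated but never counted as an event.

Events are matched across a case's samples by key (class, chromosome,
arm-or-gene, direction) and reciprocal overlap ≥ 0.5. A matched cluster is
**differing** when it is absent from at least one sample, when its
breakpoints shift by more than 5 Mb between samples, or when its fragment
count differs (extra chromosome breaks). With `d` differing clusters among
`n` total:

```
% differing = 100 · d / n,    ITH ⇔ d ≥ 1,    high ITH ⇔ % differing ≥ 50
```

Survival contrasts use the Kaplan–Meier product-limit estimator and the
Mantel–Cox log-rank test, implemented from first principles and
cross-checked against `lifelines` in the test suite. Because no per-case
segment data are published, a **synthetic cohort generator** reproduces the
study design (58 cases: 32 *MYCN* non-amplified, 20 amplified, 6
heterogeneously amplified; sampling designs T+T, T+LB, T+T+LB, LB+LB) with
known clonal structure, a ~30% clonal-fraction detection limit for the
liquid-biopsy sensor, and survival whose hazard depends on the true ITH
label. The published per-case table of the 22 heterogeneous cases ships as
a packaged fixture.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1   # writes results/cohort/
python analysis/02_call_events.py
python analysis/03_compare_samples.py
python analysis/04_survival_analysis.py
python analysis/05_reproduce_table2.py
```

With seed 1 this prints:

```
simulated 58 cases / 126 samples (seed 1)
ground-truth ITH: 21/58 cases (36.2%)
called 1153 events across 126 samples
SCA burden: mean 8.9, median 9.0
21/58 cases with ITH (36.2%); 5 high-ITH (>= 50% differing events)
among ITH cases: mean 2.38 differing events, mean 27.1% differing
EFS: log-rank chi2 5.66, p 0.0173; 3-year survival ITH 0.42 vs non-ITH 0.15
OS: log-rank chi2 2.42, p 0.1197; 3-year survival ITH 0.60 vs non-ITH 0.43
```

The pipeline's ITH calls recover the generator's ground-truth labels for
every case here (21/58 in both), the per-sample SCA burden lands near the
cohort the generator emulates (mean ≈ 9 SCAs), and simulated ITH cases
survive longer than non-ITH cases because the generator gives non-ITH
cases a 2.5× progression hazard.

Running the fixture reproduction (`05_reproduce_table2.py`) recomputes the
published per-case summary exactly:

```
mean total events    10.95   mean differing   3.55   mean % differing  35.40
median total events  10.00   median differing 2.50   median % differing 30.30
mean EFS months      49.18   mean OS months  57.14
high-ITH group: n=6, OS at 48 months 100%
low-ITH group:  n=16, OS at 48 months 42%
Mantel-Cox high vs low ITH: EFS p 0.0057, OS p 0.0082
```

Every case with ≥ 50% differing genomic events was still alive at 48
months — the high-ITH survival signal the analysis is built around.

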