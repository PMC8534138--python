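# Methods

## Scope and coordinate conventions

The package analyses *spatial* ITH only: samples of one patient collected
at the same time (tumour regions and/or simultaneous liquid biopsies).
Temporal comparisons (diagnosis vs relapse) and subclone-fraction
deconvolution are out of scope, as are segmentation of raw probe/read data
and any liftover between genome builds.

Internally all intervals are 0-based, half-open. SEG input is treated as
1-based inclusive and converted on read; chromosome names are accepted
with or without a `chr` prefix and normalized. Two arm/centromere tables
are packaged (GRCh38 default, GRCh37 alternative, both derived from the
UCSC cytoband centromere intervals); the build is a configuration choice
and is never inferred from the data. The packaged gene catalogue holds
*TERT* (5p), *ATRX* (Xq) for focal-event calling and *MYCN*, *ALK* (2p)
for amplification tagging.

## Event calling

Calls are made per sample against a configured baseline ploidy (diploid by
default; gain = copies above baseline, loss = below). The baseline is
deliberately not estimated from the sample: profiles are assumed to have
been called against a diploid reference upstream, and re-estimating it
from ctDNA admixtures would be a different method.

1. Touching same-state segments are merged into maximal aberrant runs;
   uncovered stretches are implicitly baseline.
2. A run covering ≥ `whole_chrom_fraction` (default 0.95) of its
   chromosome is a numerical change and emits no segmental event.
3. Remaining runs are split at the centromere; per (arm, direction) the
   fragments are pooled, and an SCA is emitted when their total length is
   ≥ `min_sca_size` (default 3 Mb), with `n_breaks` = number of disjoint
   fragments and the interval spanning the outermost fragments. The
   3 Mb boundary partitions aberrations into focal (< 3 Mb) and segmental
   (≥ 3 Mb); exactly 3 Mb is segmental. Each SCA is labelled typical /
   atypical / other by look-up of its signed arm.
4. Aberrant runs < `focal_max_size` over a catalogue gene emit an FSCA;
   focal runs over no catalogue gene are dropped from event counting
   (logged at debug level). Focal runs at amplification-level copy number
   are amplifications, not FSCAs.
5. Contiguous LOH runs at baseline copy number ≥ `cnloh_min_size`
   (default 10 Mb) emit a cnLOH event.
6. A chromosome whose piecewise profile switches state ≥
   `ctlp_min_switches` times (default 10) among ≤ 3 distinct copy-number
   states emits one chromothripsis-like (CTLP) event. This operational
   rule is a configurable stand-in: the phenomenon is reported in the
   field without printed criteria. SCAs co-located with a CTLP are still
   called independently.
7. Segments at ≥ `amplification_cn` copies (default 8 = 4× ploidy, a
   conventional amplification cut-off) emit amplification events. *MYCN*
   and *ALK* amplifications are tagged `counted=False`: they are
   diagnostic annotations, never genomic events in the ITH arithmetic.

The per-sample SCA count counts (arm, direction) entries: a fragmented arm
counts once; an arm with both a gain and a loss counts twice.

## Cross-sample matching and the ITH call

Events are grouped by key (event class, chromosome, arm — or gene for
focal/amplification events — and direction). Within a key, a valid
cluster holds at most one event per sample with every pair reciprocally
overlapping ≥ `reciprocal_overlap` (default 0.5, where reciprocal overlap
= intersection / larger length). Among valid partitions the matcher picks
the one maximizing total pairwise overlap (ties: fewest clusters, then
smallest start). Because a sample contributes at most one SCA per key,
instances are tiny; up to 10 events per key the optimum is found exactly
by pruned recursive assignment, beyond that by greedy agglomeration with
single-move refinement. A brute-force partition enumerator — an
independent code path — serves as the matching oracle in the tests.

A cluster is **differing** when (a) it is absent from at least one of the
case's samples, (b) any two members' corresponding breakpoints differ by
more than `shift_tolerance` (default 5 Mb) while still clustering — a
break-position shift, or (c) members' fragment counts differ — additional
chromosome breaks. Each differing cluster counts once regardless of how
many flags it trips, and a shifted cluster still contributes one to the
total, consistent with union counting of genomic events.

Per case: `n_total` = clusters (excluding *MYCN*/*ALK* amplification),
`n_diff` = differing clusters, `% differing = 100·n_diff/n_total`
(undefined, not zero, when `n_total = 0` — an aberration-free pair is not
evidence of homogeneity), `ITH ⇔ n_diff ≥ 1`, and
`high ITH ⇔ % differing ≥ 50` (inclusive, defined only for ITH cases).
Heterogeneous *MYCN* amplification detected by FISH (hetMNA) is carried as
an annotation and never sets the ITH flag, matching the observation that
hetMNA cases show no array-level SCA heterogeneity. Percentages are kept
at full precision and rounded half-up to two decimals only for display.

## Survival and frequency statistics

Implemented from first principles, with scipy supplying only the χ² tail
probability; `lifelines` and `scipy.stats.chi2_contingency` are used as
independent cross-checks in the tests, never as the implementation.

- **Kaplan–Meier**: product-limit estimator with right censoring; at tied
  times events are processed before censorings. `survival_at` evaluates
  the right-continuous step function ("3-year"/"5-year" read as exactly
  36/60 months).
- **Log-rank**: unweighted Mantel–Cox (the default log-rank of standard
  statistical packages), observed-minus-expected over pooled event times
  with hypergeometric variance, χ² with 1 df. With no events in the
  pooled sample the p-value is reported as not applicable. The
  implementation is validated against exact permutation enumeration
  (small samples), 10⁵ label shuffles (moderate samples) and a 1,000-
  replicate type-I-error calibration on null cohorts from the simulator.
- **Pearson χ²**: no continuity correction by default (matching the
  uncorrected Pearson row of standard software output); Yates correction
  available behind a flag. Zero marginal rows/columns are dropped with a
  warning.
- **Quartile comparison of SCA burden**: counts binned at cohort-wide
  empirical quartiles (ties to the lower bin), then Pearson χ² on the
  group × quartile table; fewer than four distinct counts falls back to
  distinct-value bins with a warning.

On the packaged 22-case fixture the Mantel–Cox contrast between high-ITH
(≥ 50% differing, n = 6) and low-ITH (n = 16) groups gives p = 0.0057
(event-free survival) and p = 0.0082 (overall survival) — both endpoints
significant at the 1% level, with identical numbers from `lifelines`. The
corresponding published pair is printed as 0.009/0.006; the recomputed
values match with the endpoint labels exchanged, so the tests assert
implementation–oracle agreement and significance rather than the printed
digits.

## Synthetic cohort generator

The generator emulates the study design, not array physics: aberrations
are written directly as integer-copy segments into otherwise-baseline
profiles (segmentation is upstream of this package's scope), and a single
threshold sensor stands in for array-software calling.

Per case it draws a MYCN status (defaults 32/58 non-MNA, 20/58 MNA, 6/58
hetMNA) and a sampling design (24/58 T+T, 21/58 T+LB, 11/58 T+T+LB, 2/58
LB+LB), truncal SCAs shared by all clones (Poisson, per-status means 9 /
5 / 11, matching the reported group burdens), and — in a *clonally
diversifying* fraction of cases (default 0.35) — per-region private
subclones (fraction uniform on 0.15–0.9; private events Poisson with mean
2 per region) and, for half of the diversifying liquid-biopsy cases, a
metastasis-only clone. The two-class structure is needed to reproduce
simultaneously a ~38% cohort ITH rate and the heavy-tailed differing-event
counts (1–14) of heterogeneous cases; a single Poisson rate cannot do
both. Signed arms are sampled without replacement per case from weights
shaped by the reported typical/atypical frequencies. hetMNA cases stay
truncal-only (their MYCN heterogeneity is an annotation with no SCA
consequence), and MNA cases carry a truncal *MYCN* amplification segment
whose copy number (30) exercises the exclusion rule; 2p gains in MNA
cases span the *MYCN* locus, as they do biologically.

A liquid biopsy mixes the tumour regions with Dirichlet weights, so a
region-private event reaches the ctDNA at a mixture-weighted clonal
fraction; an event enters a sample's segment file iff its effective
fraction ≥ `detection_limit` (default 0.30, the practical sensitivity of
array-based calling in admixed material). Breakpoints of every event are
jittered per sample (normal, sd 1 Mb) as measurement noise. Genuine
break-position shifts are injected explicitly (per-case probability 0.08:
one long shared event moved 6–12.5 Mb in one sample while keeping
reciprocal overlap ≥ ~0.55), because 1 Mb jitter alone essentially never
exceeds the 5 Mb shift tolerance; extra breaks likewise (probability 0.1:
one shared event split into two fragments in one sample). Non-MNA cases
carry a focal *TERT* gain or *ATRX* loss with probability 0.15, truncal or
private.

Survival: progression time exponential (Weibull behind a switch) with
hazard 0.02/month for ITH cases, multiplied by 2.5 for non-ITH cases
(reproducing the direction of the reported ITH survival advantage);
death follows progression with hazard 0.06/month, giving event-free ≤
overall survival by construction; administrative censoring at a uniform
24–130-month follow-up. With the multiplier at 1.0 the generator is an
exact null for type-I-error calibration.

All randomness flows from one seed. The clonal structure (including
jitter and shift draws) is generated *before* the detection filter is
applied, so changing the detection limit re-censors the same cohort —
this is what makes the sensor-monotonicity property exactly testable.

**Ground truth.** Per-case truth labels are recomputed analytically from
the generator's own per-sample coordinates and clonal fractions: an
occurrence is observable when its effective fraction clears the detection
limit and its jittered aberrant length clears the minimum segmental size;
observable occurrences are grouped with the same complete-linkage overlap
rule the matcher uses and flagged differing by the same absence / shift /
extra-break criteria. Truth is therefore the expected output of a perfect
caller on the generated coordinates, independent of the event-calling and
matching code paths; end-to-end recovery tests demand per-case agreement
through file round-trips.

**What the generator does not emulate** — probe-level noise and
segmentation artefacts, platform differences, FFPE quality effects,
sequence-level variation (SNVs, *ALK* mutations), subclonal nesting, and
correlated arm co-occurrence. Passing recovery tests therefore show the
pipeline is faithful to the event-level generative model, not that it is
robust to raw-array noise.

## Problem sizes in the tests

The test suite checks the event caller against an independent per-base
brute-force scan on 500 randomized two-chromosome mini-genomes (200 kb
chromosomes with thresholds scaled in proportion), the matcher against an
exhaustive partition enumerator on 200+ random small instances, recovery
on a 500-case simulated cohort, log-rank power on 100 replicate 500-case
cohorts (rejection at p < 0.01 with the 2.5× multiplier) and type-I error
on 1,000 null cohorts of 58 cases. These sizes keep the full suite around
three minutes on one CPU while leaving the Monte-Carlo bands narrow
enough to be informative.

## Known limitations

- The CTLP rule is operational; published chromothripsis scoring systems
  use allele-specific and rearrangement evidence unavailable in
  total-copy-number segments.
- FSCAs are only called over catalogue genes; a focal hit outside the
  catalogue is invisible to the event totals.
- The fixture-based survival analyses inherit the small sample size of
  the published per-case table (22 cases, 6 high-ITH); the log-rank χ²
  approximation at that size is the reason the permutation oracle exists.
- Cohort-wide aberration frequencies (per-arm percentages across all 58
  cases) depend on unpublished per-case event matrices; the operations
  that would compute them are exercised on simulated cohorts instead.
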