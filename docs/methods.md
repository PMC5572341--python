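# Methods

This note documents the models, statistics and design choices behind
`cnvherd`, in the order the pipeline runs them.

## Data model and coordinates

All genomic intervals are held 1-based inclusive internally (the PennCNV
`.rawcnv` convention, so `length = end − start + 1`); BED files are
converted to/from 0-based half-open at the I/O boundary.  Only cattle
autosomes (chromosomes 1–29) are modelled: sex chromosomes are excluded
from array CNV calling because dosage differs between sexes, and `.rawcnv`
records on chrX/chrY are skipped and counted at parse time.

## Signal layer

**PFB.**  The population frequency of the B allele is the per-probe
arithmetic mean of BAF across the cohort.  It is an input required by
HMM-based callers and a convenient cohort summary; no shrinkage or
genotype-aware estimation is attempted.

**GC-wave adjustment.**  Long-range "waves" in LRR correlate with regional
GC content.  Each sample's LRR is regressed (OLS) on the probe-level GC
fraction of the surrounding 1 Mb window, and the mean-centred fitted
component is subtracted.  The centring makes the operation exactly
mean-preserving and idempotent; a constant GC track makes the regression
degenerate and the input is returned unchanged.  A single linear term is
used rather than a spline: at the cohort sizes targeted here the linear
component dominates, and the operation is trivially auditable.

**Sample QC.**  Three per-sample statistics, thresholds configurable with
defaults LRR SD ≤ 0.30, BAF drift ≤ 0.002, wave factor ≤ 0.05:

- *LRR SD* — sample standard deviation (ddof = 1) over all probes.
- *BAF drift* — fraction of probes with BAF in the open intervals
  (0.2, 0.25) ∪ (0.75, 0.8).  A raw BAF standard deviation is also computed
  and reported but not thresholded: the diploid BAF distribution is
  tri-modal (bands at 0, ½, 1) with SD ≈ 0.4 for every sample regardless of
  quality, so a small SD threshold on raw BAF would reject everything and
  cannot be what a QC screen intends.  The drift fraction is the standard
  array-QC alternative.
- *Wave factor* — SD (ddof = 1) of per-window median LRR over
  non-overlapping 1 Mb windows within chromosomes; 0 when fewer than two
  windows exist.  This statistic has a sampling-noise floor of about
  `1.25 · σ_LRR / √(probes per window)` (the SE of a window median), which
  is why the synthetic genome uses realistic probe density (5 kb spacing,
  ~200 probes per window): at sparse toy densities the floor alone exceeds
  the 0.05 threshold and the statistic stops measuring waviness.

A sample passes iff all three statistics are at or below threshold; the
pass set therefore shrinks monotonically as any threshold is lowered.

## CNV calls and burden

Calls below 3 probes are discarded (single- and two-probe calls are the
dominant artifact mode on arrays).  A call is a *singleton* iff no call
from a *different* sample overlaps it by ≥ 1 bp on the same chromosome;
overlap within one sample does not count.  Per-sample burden records
counts, cumulative lengths, and the genic subsets (≥ 1 bp overlap with a
gene interval; genic deletions are the copy-state < 2 subset).

**Outlier removal.**  Within each breed represented by more than five
samples, a sample is dropped when its CNV count or cumulative length falls
outside mean ± 3 SD of the breed's *other* samples (union over the two
metrics).  The leave-one-out statistics are deliberate: with the candidate
included, the largest achievable deviation in a breed of *n* samples is
`(n−1)/√n` SD — below 3 for all n ≤ 9 — so an include-self 3 SD rule could
never remove anything at typical breed sizes and the screen would be
vacuous.

**Group comparison.**  CNV counts are compared across breed groups with the
tie-corrected Kruskal–Wallis test and cumulative sizes with one-way ANOVA
(counts are skewed and discrete; sizes are closer to normal after
aggregation).  When an overall test is significant at α = 0.05, all
pairwise Mann–Whitney (counts) and two-sample t-tests (sizes) are run with
Bonferroni correction (multiply by the number of pairs, cap at 1).
Mann–Whitney uses exact enumeration when both groups have ≤ 8 samples and
no ties, and the normal approximation with tie and continuity correction
otherwise.  All tests are delegated to scipy.stats.

## CNV regions

A CNVR is a connected component of the per-chromosome ≥ 1 bp overlap graph
of calls, kept when its calls come from ≥ 2 distinct samples; single-sample
components are returned separately as singleton clusters.  Because
components are maximal, CNVR spans on one chromosome are pairwise disjoint
and every call belongs to exactly one component.  Whether same-sample
overlapping calls are merged beforehand does not change the result: they
land in the same component either way and support counts use distinct
samples.  Classes: *loss* if every member call has copy state < 2, *gain*
if every member > 2, else *complex*.  The implementation is a sorted sweep;
it is verified exactly (spans, supports, classes) against an independent
base-pair bitmap union-find oracle on 1,000 random instances.

**Frequency display.**  Cohort frequency is
`100 · |supporting samples| / cohort size`.  Displayed values are
*truncated* to two decimals (e.g. 145/149 → 97.31), matching the
convention of published CNVR tables; the raw value is retained for any
thresholding such as "frequency > 5%".

**Overlap accounting.**  For each named reference set, the report counts
reference intervals overlapping any CNVR by ≥ 1 bp and the intersection
length between the reference union and the CNVR spans, expressed relative
to the reference union's cumulative length (the reciprocal normalisation is
a one-line change; the reference-relative form is the one used in published
comparison tables).  A CNVR is *novel* iff it overlaps no interval in the
union of all reference sets.  Segmental-duplication sets are pre-filtered
to length strictly greater than 5 kb (an interval of exactly 5,000 bp is
excluded).

## V_st

For one probe and groups A, B:

    V_T  = population variance (denominator n) of LRR over A ∪ B
    V_S  = (n_A·V_A + n_B·V_B) / (n_A + n_B)
    V_st = (V_T − V_S) / V_T          (0 when V_T = 0)

Population variances and the size-weighted V_S make identical group
distributions give exactly 0 on finite samples, and by the law of total
variance guarantee V_T ≥ V_S, so the default statistic lies in [0, 1].  An
unweighted-V_S variant is available (`weighted=False`); with unequal group
sizes it can go negative and is retained unclamped.  The orientation
(V_T − V_S)/V_T is the standard one for which 0 means no differentiation
and 1 complete differentiation; the sign-flipped form sometimes seen in
print contradicts that range and is not used.  V_st is computed on
GC-adjusted LRR when GC values are available.

**Run scanning.**  Differentiated regions are maximal runs of ≥ 3
consecutive same-chromosome probes with V_st strictly above the threshold
(default 0.35) — equivalent to sliding 3-probe windows with single-probe
shift merged by overlap.  Raising the threshold can only shrink run
coverage.  A CNV or CNVR is flagged differentiated only when its span
contains the *entire* run.

**Sex-dosage filter.**  Sequence from a sex chromosome mis-assembled onto
an autosome distorts the male/female dosage ratio; when groups differ in
sex composition this mimics population differentiation.  For each run,
every sample's mean LRR over the run's probes is compared between sexes
with a two-sided Mann–Whitney test, Bonferroni-adjusted across all runs
tested; a run is flagged an artifact when the adjusted p < 0.05.  With
fewer than two samples of either sex the run is marked untestable rather
than silently passed.  A rank test was chosen over visual inspection so the
filter is automatic and reproducible; it is a design decision of this
package.

## Clustering

Samples are encoded as binary CNVR presence/absence vectors (1 iff the
sample supports the CNVR).  Dissimilarity is 1 − Jaccard index of the
presence sets; two empty profiles are defined as identical (distance 0),
since the Jaccard index is undefined there and "no CNVRs" is a shared
phenotype.  UPGMA joins the closest pair, with new distances the
size-weighted average of member distances and node height half the joining
distance; ties are broken on the lexicographically smallest pair of cluster
representatives (each cluster represented by its smallest sample id), so
input order never affects the tree.  Trees are ultrametric by construction
and exported as Newick with branch lengths.  The implementation is
cross-checked against scipy's average-linkage cophenetic distances.

## Synthetic cohorts

The generator emulates the data model of an array-based cattle CNV cohort:

- probe map: `n_chroms × probes_per_chrom` probes at fixed spacing
  (defaults 2 × 2,000 at 5 kb — 10 Mb chromosomes at realistic array
  density) with a smooth GC track;
- genotypes: per-probe population B-allele frequency ~ U(0.05, 0.95),
  Hardy–Weinberg genotypes per sample;
- copy number: each catalog polymorphism (≥ 3 probes, state ∈ {0, 1, 3, 4})
  draws carriers independently per sample with its group-specific
  frequency; truth calls are recorded exactly, optionally with ± 1 probe
  boundary jitter;
- LRR: copy-state means 0 → −3.0, 1 → −0.66, 2 → 0.0, 3 → +0.40,
  4 → +0.68 (standard Illumina-array working values, overridable), plus a
  per-sample GC wave (random coupling to the standardized GC track,
  SD 0.02) and Gaussian noise (SD 0.15; designated noisy samples 0.5);
- BAF: band centre = B-dosage / copy number, with each retained or
  duplicated chromatid carrying B at the sample's allelic fraction — so
  one-copy deletions lose the heterozygous band, three-copy gains split it
  toward 1/3 and 2/3, and homozygous deletions give uniform noise;
- sex artifact: designated probe ranges receive a fixed +0.3 LRR offset in
  males only.

All randomness flows through one seeded generator; a fixed config
reproduces byte-identical outputs.  The generator does *not* model linkage
disequilibrium between probes, raw R/theta intensities, batch effects, or
an HMM caller's boundary uncertainty beyond the optional jitter — so
passing tests demonstrate correctness of the population-analysis layer on
calls of known provenance, not end-to-end calling accuracy on real arrays.

## Problem sizes, tolerances and degenerate inputs

- Replicated properties use 100 replicates (V_st recovery, UPGMA
  separation) or 1,000 (null calibration, CNVR-oracle equivalence); the
  demonstration cohort is 100 samples × 4,000 probes.  These sizes give
  stable Monte-Carlo estimates while keeping the full suite in minutes on
  one core.
- Monte-Carlo calibration checks compare empirical rates to nominal ones
  within 3 binomial standard errors; hand-computable values are asserted to
  1e-10, mean preservation to 1e-10, idempotence to 1e-8.
- Degenerate inputs are defined rather than crashed on: V_T = 0 → V_st = 0;
  constant GC → adjustment skipped; < 2 windows → wave factor 0; empty
  reference set → zero report; both-empty profiles → distance 0.  Errors
  are raised where a statistic is undefined (< 2 probes for an SD, < 2
  samples per group for V_st or group tests, zero cohort size).

## Known limitations

- The CNVR definition is the common transitive-union one; long chains of
  partially overlapping calls can produce regions much longer than any
  member call.
- V_st significance is a fixed threshold, not a permutation test, matching
  common practice for intensity-based differentiation scans.
- The sex filter tests mean LRR per run; very short runs have limited
  power, and a run can be "untestable" in single-sex cohorts.
- Burden comparisons assume samples are independent; relatedness within
  breeds is not modelled.
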