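# Methods

## The CSLV characterization

Chromosomal-scale length variation (CSLV) summarises germline copy-number
state over large genomic spans. The primary observable is the per-SNP log2
intensity ratio ("l2r") against the two-copy expectation; the CSLV feature
of a span is the arithmetic mean of the observed l2r values inside it, a
proxy for the effective "length" deviation of that piece of chromosome.
Zero is the nominal diploid length; negative values indicate net loss,
positive values net gain. Because the features are germline they do not
change with age, and age is deliberately excluded from the feature schema
(`LabeledDataset` rejects age-like columns).

Two span layouts are built in:

* **quarter-chromosome layout** — each of the 22 autosomes tiled into 4
  equal-width spans (88 features, `<chrom>_q<0..3>`), used with per-SNP
  l2r matrices; the X chromosome is excluded on this path;
* **whole-chromosome layout** — chromosomes 1–22 plus X as single spans
  (23 features), used with SEG-style segment calls.

Partitioning is by base pairs against declared chromosome sizes (UCSC
chrom.sizes; GRCh38 lengths ship with the package). With length
L = k·w + r, the first r spans get w+1 bp — span widths never differ by
more than 1 bp and the tiling is exact. An alternative layout from the
observed probe extent is available (`observed_extent_sizes`) for arrays
whose coverage stops short of the assembly ends.

### From l2r matrices

The feature is the mean over non-missing probe values whose position falls
in the span (1-based positions, half-open spans internally). Missing cells
are excluded from the mean, not imputed. A span with no observed probes
gets 0, the diploid expectation.

### From segment calls

SEG records carry a segmented mean = log2(copies/2) over an interval.
Pipelines that emit such calls leave normal regions unrecorded, so
uncovered base pairs contribute the gap value 0 (diploid) to the
length-weighted mean:

    feature = [ Σ overlap_bp × segment_mean + uncovered_bp × gap ] / span_width.

Overlapping records for one sample are resolved by later-record
precedence — a robustness rule only, since upstream segmentation emits
disjoint intervals; records extending past the declared chromosome length
are clipped with a warning. Whether a whole-chromosome value should be the
length-weighted mean or just the dominant segment's mean is genuinely
ambiguous for such data, so both are implemented (`policy="weighted"`,
the default, and `policy="longest"`); with near-complete single-segment
coverage they agree to within the uncovered fraction.

## The synthetic cohort generator

The generator exists to give the pipeline inputs with known ground truth;
its defaults are the package's reference study conditions.

**Latent state.** Person p carries a true offset δ[p,s] ~ N(0, τ) for
each partition segment s, independent across segments and people
(τ = `person_segment_sd`, default 0.1 l2r units — a scale at which
single-segment effects are invisible to the eye but jointly informative).
The independence and Gaussianity are modelling assumptions, not estimates:
the empirical distribution and correlation of real CSLV values are not
publicly characterized, so the simplest testable structure is used.

**Risk.** Case probability follows a logistic model on the offsets:
linear terms (segment → coefficient) plus optional pairwise products
(nonlinear interactions). The intercept is never user-set; it is
calibrated by Brent root finding so the mean predicted probability matches
the target prevalence to 1e-6 (closed form logit(p) for the null model).
Labels are Bernoulli draws. The named **strong** condition uses 16 linear
terms (coefficient ±10 ⇒ one log-odds SD each at τ = 0.1) on chromosomes
1–16 plus 4 interactions (coefficient ±50 ⇒ ≈ 0.5 log-odds SD each) on
chromosomes 17–22 — a distributed, partly nonlinear signal in which no
single segment dominates. The **null** condition has an empty risk
function. Default prevalence is 0.25, matching a ~1:3 case/control
design.

**Rendering.** l2r matrices place `snps_per_chromosome` probes (default
400) at evenly spaced 1-based positions; each probe reports its segment's
δ plus N(0, σ) noise (σ = `snp_noise_sd`, default 0.2, a realistic
per-probe noise floor well above τ). A quarter-chromosome span then
carries m = 100 probes, so the feature noise is σ/√m = 0.02 < τ/3 and the
extracted features track the latent offsets at r ≈ 0.98. SEG records are
emitted per (person, segment) only when |δ| ≥ `seg_report_threshold`
(default 0.01), reproducing the unreported-normal-region behaviour of
masked CNV releases; with τ = 0.05 and threshold 0.05 the reported
fraction is 2(1−Φ(1)) ≈ 0.317, which the tests verify by simulation.

All randomness flows from one seed through named `SeedSequence` streams
(offsets, labels, probe noise, subsampling), so every operation is
deterministic and the streams are independent of call order.

**What the generator does not emulate** — LD structure, GC waves and
batch effects, allele-specific intensities, population stratification,
correlated offsets across segments, and realistic per-probe missingness.
Passing tests therefore demonstrate that the pipeline recovers the signal
it defines, not that real cohorts carry such a signal.

## Classifiers and evaluation

Base families are standard library estimators behind one factory:
lightgbm gradient boosting (200 trees, learning rate 0.05, 15 leaves),
a 2×32 rectified feedforward net with early stopping on a 10% validation
slice, ridge-regularized logistic regression, and a random forest; the
scale-sensitive families are wrapped with standardization. The package's
own estimator is the **super learner**: stratified k-fold (default 5)
out-of-fold base probabilities feed a logistic meta-learner, which
therefore never sees in-fold predictions; bases are refit on the full
training data for scoring. A fold whose training part is single-class
triggers a reshuffle with a new derived seed (at most 5 attempts). No
time-budgeted model search is performed: a fixed grid per family plus the
stacked ensemble is enough to measure synthetic-signal recovery, which is
what this package evaluates.

AUC is the pair-counting (Mann–Whitney) estimate with ties credited 0.5,
computed from rank sums; the test suite pins it to trapezoidal ROC
integration at 1e-12. Repeated evaluation draws seeded stratified splits
(default 10 repeats, 15% held out), refits a fresh clone per repeat, and
summarises the held-out AUCs with a one-sample t-interval; Shapiro–Wilk
normality of the repeat AUCs is reported and warned on, never enforced.

**A caveat the coverage simulations expose.** Repeat AUCs from overlapping
splits of one dataset are positively correlated: as repeats grow the
t-interval concentrates on the *dataset-conditional* AUC, which deviates
from the population value at finite n, so nominal 95% coverage degrades.
With few repeats (wide intervals) or stochastic learners (extra
between-repeat variance) coverage is near-nominal — the null-cohort tests
run in that regime — but tight intervals from many repeats of a
deterministic learner on one dataset should be read as precision of the
conditional estimate, not of the population AUC.

## Decile risk stratification

The held-out set is ranked by score (stable descending sort, ties by
input order) and cut into ten deciles. With n = 10q + r the top decile
gets q members and deciles 2..r+1 absorb the remainder — for n = 889 that
is 88 in the top decile and 89 elsewhere, matching the published held-out
table this convention was checked against. Each decile's odds ratio is
taken against the **whole** test set (decile included):
OR_d = (a_d/b_d)/(A/B), read as "times more likely than the average
person in this set"; the pooled table has OR = 1 by construction. The 95%
interval is Woolf's log-normal approximation with
SE = √(1/a_d + 1/b_d + 1/A + 1/B); any zero count triggers the
Haldane–Anscombe 0.5 correction with a warning, and b_d = 0 makes the OR
infinite (flagged, not an error).

Woolf was chosen because it reproduces the published intervals where they
are internally consistent (deciles 2 and 3 exactly at printed precision;
R's `fisher.test` does not). The published decile-4 upper bound of 1.0
corresponds to exponentiating around the odds ratio at its printed
precision (0.59 · e^{z·SE} = 1.049 → 1.0), whereas the exact computation
gives 1.051 → 1.1; the package computes the exact value and the tests
document the rounding route. The published top-decile interval (9.3–30.3
vs exact Woolf 9.2–30.9) likewise reflects source-side rounding and is
not chased.

`top_fraction` counts cases in the top ⌊n·fraction⌋ ranked samples
(consistent with the smallest-on-top decile convention); feature
importance uses exact TreeSHAP contributions from the lightgbm booster
(mean |contribution| per feature, signed per-sample matrix retained, and
the additivity identity Σ contributions + base = raw margin is tested at
1e-6) or, for non-tree models, the mean drop in pair-counting AUC over 10
seeded column permutations.

## Cohort rules and numerical conventions

Biobank-style rules: cases are women flagged for breast cancer by both
self report and registry; controls are women with no cancer flag of any
kind; everyone else is dropped. Atlas-style rules: cases are women with
breast cancer, controls women with any other cancer; men are dropped.
Rule application is order-independent and idempotent.

Coordinates are 1-based inclusive on disk (SEG convention) and 0-based
half-open in memory. Chromosome names are normalized by stripping a
leading `chr` and uppercasing X; Y is rejected (masked germline CNV
excludes it and no operation here is defined for it). l2r matrices are
headerless with a sidecar sample list (IDs are distributed separately in
the biobank release this dialect mirrors); `NA`/empty tokens are missing;
malformed rows raise errors naming file and line. Feature tables are
written at 12 significant digits (round trip < 1e-10); l2r matrices at 17
(bit-exact round trip). Default split: 15% held out — on a ~5,900-person
cohort that is a test set of ~889, the size of the published held-out
table — stratified by label to stabilize AUC variance at moderate
prevalence.

## Problem sizes used by the test suite

The suite exercises the full pipeline at sizes chosen to finish on a
single CPU in a few minutes: the strong-signal end-to-end run uses 6,000
people × 88 features with 10 repeated splits of the stacked ensemble; the
null-calibration run uses 1,200 people with 5 repeats; coverage and
permutation nulls use hundreds of samples. Larger cohorts change none of
the code paths — only the tightness of the statistics.

## Known limitations

* The Gaussian independent-offset generator is an assumption, flagged as
  such; real CSLV correlation structure is unknown here.
* Repeated-split t-intervals under-cover for many repeats of a
  deterministic learner (see above).
* The segment path's later-record-precedence rule is arbitrary for truly
  overlapping calls; upstream segmentation should make it moot.
* No GC correction, probe QC, or segmentation is performed; inputs are
  taken as given.
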