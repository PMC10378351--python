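# Methods

## Pipeline model

The package classifies *pairs* of patients rather than single profiles.
Given TPM vectors `x_i` for patients with strictly distinct survival times,
every unordered pair `{i, j}` with `surv(i) > surv(j)` yields

* a TLS vector `x_i − x_j` (the expression pattern of longer survival), and
* a TSL vector `x_j − x_i` (its negation),

so positives and negatives are exactly balanced and chance accuracy is 0.5.
The binary TLS/TSL classifier is the learned object; survival-interval
prediction reduces to four such comparisons against reference patients.

### FPKM → TPM

`TPM_ij = FPKM_ij / Σ_i FPKM_ij × 10⁶`. FPKM already normalizes transcript
length, so the conversion is pure per-column rescaling; no further length
division is applied. Consequences used by the tests: every TPM column sums
to 10⁶ (relative tolerance 1e−6), the map is idempotent, and it is
invariant to per-sample rescaling of the input. All-zero columns are
rejected rather than silently propagated. Zero-expression genes are *not*
filtered; the full gene vector is kept so the image geometry is fixed.

### Cohort screening

Three ordered stages, each reported with its exclusion count so that
`n_input = n_output + Σ exclusions`:

1. records missing age or survival time, or with negative survival (such
   values cannot be ordered and are treated as data errors), are dropped;
2. every record whose survival time is shared by ≥ 2 records is dropped —
   whole tie groups, never deduplicated — guaranteeing the strict total
   order pair generation needs and making downstream tie-breaking
   unnecessary;
3. optionally, records without an actual death date are dropped (censored
   "survival" values are last-follow-up dates, a different quantity).

### Stratified splitting

Patients are stratified at an age cutoff (≤ cutoff vs older). Within each
stratum the sorted ids are shuffled by a seeded `random.Random` (re-seeded
per stratum so one stratum's draw does not perturb the other) and the first
`⌈0.7·n⌉` become training. The rounding rule is configurable
(`ceil`/`floor`/round-half-up); ceiling is the default, matching realized
70/30 sizes of 49/20 and 53/22 for strata of 69 and 75. The train count is
clamped to `[1, n−1]` so both sides are populated; strata with fewer than
two members are an error.

### Dimension raising

A length-G difference vector fills the smallest square matrix
(side `s = ⌈√G⌉`, so `(s−1)² < G ≤ s²`) row-major; trailing `s² − G` cells
are zero. Values are scaled linearly per image: `pixel = ⌊255·(x − min) /
(max − min) + 0.5⌋` (round half up), with a constant vector mapping to all
zeros. Scaling is **per image** — each image uses its own extremes — which
requires no cross-image state and makes the TSL image the exact
255-complement of its TLS partner at every data cell (`min(−v) = −max(v)`,
so the linear map reflects). Storing `(min, max)` per image in the manifest
makes the quantization invertible to within half a gray step,
`(max − min)/510`. A dataset-global scaling was considered and rejected as
the default: it couples images through training-set state and breaks the
complement identity; the per-image choice is recorded here as the package's
convention. PNG output is 8-bit single-channel grayscale and lossless.

Pair generation inside the training pipeline is always within a stratum
and within one side of the train/test split: train images pair training
patients only, test images pair test patients only.

### Classifiers

The full-scale protocol this pipeline supports fixes Adam, cross-entropy
and dropout 0.4 and varies architecture and (epochs, batch size) over
{(50, 8), (100, 16), (150, 32)}. This package registers three desk-scale
architectures:

* `tiny` — a numpy implementation of conv(8·3×3)–ReLU–maxpool–
  conv(16·3×3)–ReLU–maxpool–dropout(0.4)–linear–softmax, trained with Adam
  (lr 1e−3 default; the conventional Adam default, as no value is dictated
  by the protocol) and cross-entropy. All randomness (init, shuffling,
  dropout) flows from one seeded generator, so training is bit-reproducible.
* `logreg` — L2 logistic regression on flattened pixels; deterministic and
  fast, used by the age sweep.
* `mlp` — a one-hidden-layer scikit-learn perceptron (Adam, log loss).

Heavyweight pretrained CNN families (GoogLeNet, ResNet, DenseNet, ResNeXt)
are out of scope for this library: they need GPU-scale training and the
real cohort to be meaningful, and none of the desk-scale conclusions depend
on them. The grid-search helper runs any architecture × (epochs, batch)
grid, reports the full accuracy table and breaks argmax ties by fewer
epochs, then smaller architecture.

Evaluation uses the confusion-matrix accuracy `(TP+TN)/(P+N)` with TLS as
the positive class; this equals the mean per-image correctness indicator.

### Age sweep

For each cutoff in the sweep range (default 48–69, the age quartiles of the
motivating cohort): split, build per-stratum train and test image sets,
merge across strata, train one model, record test accuracy. Degenerate
cutoffs (a stratum with < 2 members, or a single-class training set) are
skipped, not fatal. The argmax cutoff is reported with ties broken toward
the smaller age.

### Interval prediction

Reference selection: ages whose held-out accuracy exceeds 0.7 are eligible;
for each boundary (182, 365, 1095, 1825 days ≈ 6 mo, 1 y, 3 y, 5 y) the
eligible patient with survival nearest the boundary is chosen (ties by
smaller distance then lexically smaller id; a patient is never reused), and
the four survivals must end up strictly increasing. Four references are the
minimum that brackets five ordered outcomes, which is why the boundary
interpretation is adopted: the predicted bin index is the number of
references the patient is called longer-surviving than. Calls that are not
of the form longer…longer, shorter…shorter are resolved by that same count
and flagged `consistent=False`. The five bins partition the time axis as
half-open intervals `[0,182), [182,365), [365,1095), [1095,1825), [1825,∞)`.
Prediction images use exactly the training-time encoding (patient − reference,
TLS orientation, per-image scaling).

## Synthetic data generator

Per patient `p` and gene `g`, on the natural-log scale:

```
log x[g,p] = mu_g + s_g · effect_size · noise_sd · t_p + eps,
eps ~ N(0, noise_sd²),   mu_g ~ N(baseline_log_mean, baseline_log_sd²)
```

with `s_g ∈ {−1,+1}` for signature genes (a `frac_signal_genes` fraction)
and 0 otherwise, and `t_p = z_p`, the standardized survival rank. Defaults:
40 patients × 400 genes (20×20 images), 25% signature genes, effect size 2
(in residual-SD units per rank-SD — strong enough that the desk-scale CNN
separates classes clearly), `noise_sd` 0.4, baseline log-mean 2 and log-SD 1
(a right-skewed expression distribution spanning roughly two orders of
magnitude, qualitatively like bulk RNA-seq abundance), ages uniform on
26–90 and survival uniform without replacement on 1–3000 days (so survival
times are distinct by construction). Deliberate defects are opt-in:
`tie_fraction` copies survival values between disjoint patient pairs (the
ground truth records every tie member, so filter bookkeeping is exactly
checkable), `missing_fraction` blanks age or survival alternately, and
`death_date_fraction` controls the censoring flag.

**Planted age break.** With `planted_age_break = a*`, patients aged ≤ a*
get a constant offset added to their signature activation:
`t_p = z_p + B·[age ≤ a*]` with `B = age_break_offset = 4` rank-SDs — an
age step in the baseline expression of the prognostic signature. Same-group
pairwise differences cancel the step and stay survival-informative;
cross-group differences are dominated by it, and because the longer member
of a cross pair is equally likely to sit on either side of the step, cross
pairs carry essentially no label information. The stratified pipeline's
accuracy therefore peaks exactly at `a*`. Two simpler designs were
evaluated and rejected: silencing the signature below the break leaks the
signal patient's own rank through every mixed pair (~0.75 accuracy),
rewarding cutoffs *below* the break; and giving each age group its own
independent gene module makes same-group and cross-group score
distributions identical for any linear classifier (no peak at all).
`B = 4` comfortably exceeds the ±1.7 range of standardized ranks, so
cross-pair scores are sign-dominated by the step.

**What the generator does not emulate:** count noise (negative-binomial
mean–variance), gene–gene correlation beyond the planted signature,
molecular subtypes, batch effects, or any realistic age–survival joint
distribution. Passing tests therefore demonstrate that the pipeline's
mechanics (counting, geometry, balance, bin logic) are correct and that the
image encoding preserves a rank signal a CNN can learn — not that any
particular accuracy is attainable on real tumors.

## Problem sizes used by the test suite

The suite favors the smallest sizes that make each property visible:
geometry checks use the full G = 60,483 without training; learnability uses
40 patients × 400 genes with a plain patient-level 70/30 holdout (756
training images), the compact net, 15 epochs, batch 16, averaged over three
seeds; the age-break recovery and null-flatness sweeps use 120 patients,
ages uniform on 50–70, cutoffs 55–65, with the linear classifier, averaged
over three seeds. Replicate aggregation is by the mean curve/accuracy over
seeds. In design pilots the break recovery located the planted cutoff
exactly in 12 of 12 seeds and the null mean-curve range stayed below 0.15
in all replicate triplets.

## Known limitations

* The printed full-scale accuracies of the motivating study are not
  reproducible here by design (real cohort, GPU-scale training); the
  package substitutes calibrated synthetic benchmarks.
* The mapping from four references to five bins is a reconstruction — it is
  the only arrangement in which four ordered binary outcomes bracket five
  intervals — and reference identities are necessarily synthetic.
* Per-image scaling discards the absolute magnitude of differences; only
  the stored `(min, max)` manifest entries make images comparable on a
  common scale.
* `evaluate_by_age` attributes an image's correctness to both patients of
  the pair; ages sharing patients are therefore correlated, which is
  acceptable for the thresholding use it serves.
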