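# Methods

## The PHI connectivity statistic

For an electrode pair (A, B), the amplitude traces (µV) of the analysis
epoch are discretized by rounding to bins of width 10 µV: the state of
sample *x* is ⌊x / 10 + 0.5⌋, i.e. the nearest multiple of 10 µV with
half-way values rounded toward +∞. The rounding rule matters only at bin
boundaries but is fixed and configurable (`bin_width`); amplitudes are not
mean-centered before binning. Probabilities are the observed relative
frequencies of states (and state pairs, matched by time stamp) over the
epoch — plug-in estimates with no smoothing and no bias correction
(Miller–Madow and friends are deliberately omitted: the statistic is defined
by the plain empirical procedure). All entropies use log base 2; `0·log 0`
contributes 0.

Mutual information is combined from the three entropies,
MI = H(A) + H(B) − H(A,B), and PHI is the sum of MI taken with A as source
and with B as source. Because both directions use the same empirical
distributions, the two terms are identical and PHI = 2·MI; the
implementation still computes both and asserts their equality to 1e−9,
treating the directional notation as vestigial rather than as a
perturbation-based (maximum-entropy source) computation, which the empirical
procedure does not support.

The analysis epoch is the first 60 s of the preprocessed recording,
anchored at sample 0 (the only defensible reading of "first epoch" absent a
stated offset). Epoch extraction is idempotent, and recordings shorter than
the epoch are rejected with the available duration in the error.

Default pairs: the 13 DMN pairs of the 10–20 montage listed in the README,
in that canonical order. Channel labels are normalized to canonical 10–20
capitalization; the modern temporal labels T7/T8/P7/P8 are mapped to
T3/T4/T5/T6.

## Feature table

Features are the 13 PHI values, min-max-scaled age, and sex. Scaling and
coding conventions:

- **age_scaled** = (a − min)/(max − min), computed over exactly the subjects
  in the table. Since each pairwise contrast is trained only on its two
  groups, the scaling is fit per contrast. It is fit on the full table
  before cross-validation — replicating the reference procedure, which
  scales age as a preprocessing step — and therefore leaks the test
  subject's age bound into training; `loocv_svm(...,
  scale_age_within_training_folds=True)` provides the leakage-free variant
  (min-max scaling is affine-invariant, so re-scaling the scaled column
  within a training fold is exact). Degenerate age columns scale to all
  zeros with a warning.
- **sex**: male = 1, female = 0. The coding is arbitrary but fixed for
  reproducibility; parsing is strict.
- PHI features enter the SVM unscaled; no standardization is applied by
  default, matching the reference pipeline which scales only age.

## Classification

Sigmoid-kernel SVM (`tanh`), one model per LOOCV fold: for *n* subjects,
*n* fits on *n*−1 subjects each. Hyperparameters are not dictated by the
problem and are fixed at C = 1, `gamma='scale'`
(1 / (n_features · Var(X))), coef0 = 0; all are exposed in `SvmConfig` and
recorded in the CLI's results files. libsvm on a fixed binary problem is
deterministic, so repeated runs give identical predictions.

Metrics derive from the pooled confusion matrix; the positive class is the
first-named group of a contrast (AD in AD–HC, FTD in FTD–HC, AD in AD–FTD).
The default averaging is support-weighted over both classes, under which
weighted recall equals accuracy identically — the signature needed for a
report whose recall column duplicates its accuracy column;
`positive_class` mode gives the clinical-style one-sided metrics. A zero
denominator yields 0 with a warning rather than an exception, so degenerate
folds don't abort batch runs.

## Permutation importance and refinement

Baseline = LOOCV accuracy on the intact table. For each feature and each of
50 iterations, the feature's column is shuffled across subjects (whole-table
permutation, then full LOOCV re-evaluation — the simplest reading of
"accuracy change when permuting"; per-training-fold permutation is out of
scope) and the decrease from baseline recorded. The report carries the mean
and the SD across iterations per feature. Ranking is by descending mean
decrease with ties broken by the table's canonical column order;
refinement keeps the top k (k = 8 is the reference configuration for
AD–FTD, not a hard-coded constant). Demographic features are permutable
like any other.

Two properties worth stating precisely. Permuting a constant column is a
no-op, so its decrease is exactly 0 on every iteration. A duplicated signal
column, by contrast, is *not* ignored by a kernel SVM — both copies enter
the kernel — so permuting one copy produces a real (but softened) decrease;
the test suite asserts the softening, not a zero.

## Synthetic cohorts

The generator emulates the structure of the clinical study: 88 subjects
(AD 36 / FTD 23 / HC 29), 19 channels of the 10–20 montage, 60 s at 500 Hz,
ages from group-specific normals truncated to [40, 95] (means/SDs
66.39 ± 7.89, 63.60 ± 8.20, 67.90 ± 5.40), sex Bernoulli with group male
proportions 12/36, 14/23, 18/29. Per-subject generators are seeded
`master_seed + subject_index`, so extending a cohort never reshuffles
existing subjects.

Coupling model: each coupled pair p gets an independent latent standard
normal s_p; channel c mixes √ρ_p·s_p over the pairs containing c plus
independent noise weighted √(1 − Σρ) to restore unit variance, then scales
to `amplitude_scale` (default 50 µV SD). For a pair whose channels share no
other pair, corr = ρ and the true MI is −½·log₂(1−ρ²) bits — the closed
form used as an estimator oracle. The model is stationary within a
recording (the analysis uses a single epoch) and spectrally white: no 1/f
shape, alpha peaks, artifacts or nonstationarity. Consequences: passing
tests demonstrate the estimator, classifier and importance machinery on
controlled coupling, not robustness to real EEG's spectral structure or
artifacts.

Default per-pair coupling is calibrated from a reference per-pair
connectivity profile (the clinical cohort's published group means per
pair), mapped monotonically onto ρ through an affine map into [0.08, 0.30].
The ceiling is forced by the hub constraint — Fp2 participates in four
pairs and each channel's total coupling must stay below 1 — so absolute
synthetic PHI sits near 0.1 bits instead of the clinical 3–4 bits, while
the per-pair group *orderings* (frontal pairs depressed in both dementias,
temporal–parietal pairs depressed in FTD) are preserved. Two knock-on
effects are documented rather than hidden: (i) group separations are weak,
so LOOCV accuracies on the default cohort are modest (and FTD–HC can fall
below chance); (ii) with PHI features at ~0.1 and demographics at ~1, the
unscaled kernel weights demographics heavily, so age/sex can top the
importance ranking on synthetic cohorts — on clinical data the magnitudes
are reversed. The planted-pair recovery experiment (two 20-subject groups
differing only in the O1-O2 coupling, ρ 0.1 vs 0.9) shows the pipeline at
full strength: LOOCV accuracy 1.0 and the planted pair ranked first.

## Numerical choices

- Binned-MI vs Gaussian closed form: tolerance 0.05 bits at
  ρ ∈ {0.3, 0.6, 0.9} (n = 30000, scale 50 µV, ~40 populated bins), frozen
  from a pilot oracle run (observed |err| ≤ 0.03, dominated by the plug-in
  bias ≈ K/(2n ln 2)). At ρ = 0.99 the conditional spread
  50·√(1−ρ²) ≈ 7 µV falls below the bin width and discretization loses
  diagonal information; the pilot showed a ≈ −0.21-bit deficit, so that
  example's tolerance is 0.25 bits.
- Plug-in MI is clipped at 0 to absorb floating-point round-off.
- Exhaustive oracle agreement (naive frequency-table implementation) is
  required to 1e−12 on sequences over ≤ 5 symbols, length ≤ 12.
- Importance ties break by canonical column order; all RNGs are
  `numpy.random.default_rng` with explicit seeds.

## Problem sizes

The test suite and the acceptance script run the full 88-subject cohort at
the native 60 s × 500 Hz once each, the 40-subject recovery cohort with
50-iteration importance, and shorter epochs (2–10 s) where only bookkeeping
is under test; the complete suite runs in roughly two minutes and the
acceptance script in about five on one CPU.

## Limitations

- The empirical PHI reading makes the two directional MI terms equal;
  directed (perturbation-based) variants are not implemented.
- No epoch averaging: a single 60-s epoch per subject, as in the reference
  procedure; time-resolved PHI is out of scope.
- The SVM hyperparameters behind the reference accuracies are not
  recoverable; reported clinical-scale numbers therefore depend on the
  defaults documented above.
- The generator cannot reach clinical PHI magnitudes under pairwise
  Gaussian coupling (a hub channel would need Σρ > 1); strong global
  components such as volume conduction are deliberately not modelled.
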