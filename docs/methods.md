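# Methods

This note records the modelling choices behind `ctglearn`: what each
stage computes, the conventions adopted where several readings were
possible, and what the synthetic cohorts do and do not establish.

## Signals and preprocessing

An FHR record is a beats-per-minute series at 4 Hz, at most ~90 minutes,
with dropouts (zero-valued or non-finite samples, carried internally as
NaN). Preprocessing interpolates first and filters second, since the
filter needs a gapless signal.

* **Gap filling** uses PCHIP (monotone cubic Hermite) between bracketing
  observations — shape-preserving, so fills never overshoot the
  bracketing samples; leading/trailing gaps take the nearest observed
  value (a Hermite segment needs knots on both sides). Observed samples
  are never altered.
* **Filtering** is a 6th-order low-pass Butterworth, cutoff 0.034 Hz
  (taken as a literal frequency; both order and cutoff are
  configurable), applied forward and reverse (`sosfiltfilt`) for zero
  phase and unit DC gain. Edge padding is ten cutoff periods
  (10·fs/f_c samples, capped at N−1): at f_c = 0.034 Hz the impulse
  response spans hundreds of samples, so padding proportional to the
  filter order alone leaves visible edge transients. With this padding a
  second preprocessing pass changes an in-band signal by < 1e-6 bpm RMS.
  Note the cutoff is aggressive relative to 15-s accelerations; users
  studying short events may prefer a higher cutoff, which is why the
  value is exposed rather than fixed.

## Features

Population (1/N) standard deviations are used throughout so that
closed-form oracles are unambiguous. All thresholds on episodes are
closed (≥, ≤).

* **Baseline.** The virtual baseline mean x̄ is the plain mean; samples
  outside x̄ ± 10 bpm are clipped to the band (one pass), and the real
  baseline RBL is the mean of the clipped series.
* **Accelerations/decelerations.** Maximal runs with x ≥ RBL+15
  (respectively x ≤ RBL−15) lasting ≥ 15 s; a run of exactly 15 s
  counts. Counts are invariant to adding a constant to the signal.
* **STV.** Each whole minute is split into 24 subintervals of 2.5 s
  (10 samples at 4 Hz); the minute's value is the mean absolute
  difference of successive subinterval means, and STV averages the
  minutes. The trailing partial minute is discarded. (The printed
  definition of the subinterval count is internally inconsistent — a
  formula giving 6 per minute against a stated 2.5-s duration giving
  24 — and the 2.5-s reading is used, matching clinical STV practice.)
* **LTV.** Mean of (max − min) over non-overlapping 240-sample (60-s)
  blocks, partial block discarded; the printed prefactor that conflicts
  with the block length is resolved in favour of the block mean, the
  only self-consistent reading.
* **RMS** of the raw (unfiltered-mean) preprocessed samples.
* **SampEn(m, r).** m = 2, r = 0.2·SD by default (the field convention;
  the source leaves them unstated), Chebyshev distance, self-matches
  excluded, N−m templates at both lengths. Pairs are counted with a k-d
  tree so full-length records are tractable; the per-template
  normalisations cancel in A/B. A constant signal returns 0; B = 0 or
  A = 0 raise a degenerate-input error (the statistic is undefined or
  infinite — common for short series at tight tolerance).
* **FPeak.** Welch PSD with Hamming window, 256-sample (64-s) segments,
  50% overlap, mean removed; the DC bin is excluded from the argmax.
* **Poincaré.** The interval series is NN_n = 60/FHR_n seconds
  (beat-interval transform; a raw-sample mode exists since the
  formulae are transform-agnostic). SDSD and SDNN are population SDs of
  the successive differences and of the series; SD1 = √(½)·SDSD,
  SD2 = √(2·SDNN² − ½·SDSD²) (negative radicand clamped to 0), and
  SDRatio = π·SD1·SD2 as printed — an ellipse area despite the name;
  the plain SD1/SD2 quotient is exposed as a diagnostic but is not a
  pipeline feature. The identity SD1² = ½SDSD² holds exactly; the
  autocovariance form Y(0) − Y(1) matches when Y is computed over the
  N−1 plot pairs (`poincare_autocovariance`).
* **Box-counting dimension.** The graph is normalised to the unit
  square and covered with dyadic grids r = 2^−k; within each column the
  boxes spanned by the sampled range are counted and D is the
  least-squares slope of log N(r) vs log(1/r). The finest grid keeps at
  least 32 samples per column: below the sampling resolution the
  sampled polyline is trivially one-dimensional and the slope collapses
  toward 1 (with the cap, a line measures 1.00 and Brownian graphs
  1.43 ± 0.06 against the theoretical 1.5 — the residual bias is the
  usual finite-sample underestimate). Constant signals return 1 by
  convention; at least 512 samples are required.
* **DFA.** Integrate the mean-removed signal, detrend linearly in
  non-overlapping windows, fit log F(n) vs log n over 10 log-spaced
  scales in [4, N/4]. White noise recovers α ≈ 0.5, 1/f noise ≈ 1.0,
  Brownian motion ≈ 1.5. A constant signal (zero fluctuation at all
  scales) is a degenerate input.

## Outcome metadata

Case records carry the delivery blood-gas panel and Apgar scores; the
46-row caesarean panel is packaged as CSV. pH bands assign each case to
acidosis (pH ≤ 7.20), foetal deterioration (7.20 < pH ≤ 7.25) or
clinical decision (pH > 7.25); the inclusive 7.25 boundary is the only
reading that reproduces the panel's 18/4/24 split (pH 7.25 occurs
twice). The grouping is metadata only — classification is binary
case/control.

## Synthetic cohorts

A record is baseline + AR(1) wander + band-limited (0.03–1 Hz)
variability + Poisson-placed trapezoidal events (5-s ramps, exponential
plateau with a 20-s floor) + white observation noise, with
Poisson-placed dropouts marked missing. Accelerations and decelerations
share an occupancy mask, so inserted events never overlap and the
ground-truth list is exact; with noise off and amplitudes ≥ 20 bpm the
episode detector recovers the inserted counts exactly.

Class contrast: because the 0.034 Hz low-pass removes nearly all
fast variability, the short/long-term-variability contrast between
classes is carried by the slow in-band wander — controls wander more
(SD 8 bpm, 2-minute correlation time, echoing healthy baseline cycling)
while cases are flat and sluggish (SD 4 bpm, 4-minute correlation), with
fewer accelerations (3/h vs 8/h) and more, deeper decelerations (6/h at
25 bpm vs 1.5/h at 20 bpm). Each record scales its variability
amplitudes and event/gap rates by lognormal factors (σ = 0.8,
normalised to mean 1) to emulate between-subject heterogeneity; event
amplitudes are not scaled, preserving detector recoverability. This
calibration places the default cohort in the intended
partially-overlapping regime (random-forest cohort AUC ≈ 0.92 at
20-minute records) where the class-imbalance phenomenology appears:
near-ceiling specificity with suppressed sensitivity before
rebalancing, both recovered by SMOTE. `well_separated_params()`
provides a low-heterogeneity, high-contrast configuration for
parameter-recovery checks (AUC ≥ 0.99).

Cohort seeds fan out to per-record streams via `SeedSequence.spawn`, so
cohorts are reproducible element-wise. Case outcome rows draw pH within
the three bands with largest-remainder rounding of the configured
fractions (default 18/46, 4/46, 24/46 — exact at n = 46); BDecf/BE and
Apgar scores are derived from pH with noise and are synthetic stand-ins,
not clinical data.

What passing tests on these cohorts show — and what they do not: the
generator encodes the *feature-level* statistics the analysis assumes
(variability depression, deceleration load, class skew, dropouts). It
does not model cardiovascular physiology, uterine-contraction coupling,
sensor artefacts beyond dropouts, or the label noise of clinical
decision-making, so absolute performance numbers on synthetic cohorts
do not transfer to clinical data; directional behaviour (imbalance
suppressing recall, SMOTE recovering it, feature-subset plateaus) is
what the synthetic experiments establish.

## Resampling, selection, classifiers

* **SMOTE**: synthetic minority points x + u·(x_nn − x), u ~ U(0,1),
  x_nn among the k = 5 Euclidean nearest minority neighbours found in
  standardised feature space (so ~140-bpm baselines do not drown ~1-unit
  entropies); interpolation is done in the original scale. The 46→300
  growth is non-integral: whole per-point rounds cover the integer part
  and the remainder draws seed points without replacement. Majority
  reduction is simple random undersampling. Resampling before CV is the
  reproduced design; within-fold resampling is available and preferred
  for unbiased estimates.
* **RFE**: one random-forest fit ranks all features by mean
  impurity-decrease; each candidate size keeps the top-ranked subset
  (single-pass elimination, which guarantees size-k ⊂ size-(k+1)),
  refits and records CV sensitivity/specificity/AUC; best size
  maximises AUC with ties to the smaller subset.
* **FLDA**: w ∝ S_W⁻¹(μ_control − μ_case), bias at the projected
  midpoint of the class means; singular S_W gets a ridge
  λ = 1e-6·tr(S_W)/d (floored at 1e-8 for fully degenerate scatter).
  The midpoint rule ignores class priors, so FLDA is less prone to the
  majority-class collapse than the thresholded learners — visible in
  the imbalanced-design results. For ROC only, the signed decision
  value is mapped through a logistic link.
* **Random forest**: 500 bootstrapped, unpruned trees, ⌊√d⌋ features
  per split, Gini impurity (none of these is stated in the source; these
  are the standard defaults). The trees are grown by scikit-learn; the
  class pins the voting contract — score = fraction of trees voting
  case, majority vote with ties to control.
* **Deep net**: layers d–32–32–2, tanh hidden units, softmax head;
  loss is the printed two-term cross-entropy
  −Σ_y [t·ln O + (1−t)·ln(1−O)] averaged over examples (for a 2-class
  softmax this is twice the categorical cross-entropy; gradients are
  verified against central finite differences to 1e-5). Training is
  minibatch SGD (batch 16, 200 epochs) with momentum μ = 0.9 velocity
  updates, annealing α_t = α₀/(1 + t·r) with α₀ = 0.05, r = 1e-6, and
  inverted dropout (0.1 input, 0.5 hidden — within the stated < 0.2 and
  ≤ 0.5 bounds) active only during training; the tanh derivative is
  taken pre-dropout and gated by the mask. Weights initialise uniform
  ±√(6/(fan_in+fan_out)). Architecture and schedule are undocumented in
  the source; these defaults are assumptions, all configurable.
  Non-finite loss or weights abort training with a diagnostic.

Everywhere, the positive class is the case; a tied score (0.5) falls to
control, matching the discriminant convention that a non-negative
decision value means normal.

## Evaluation

Stratified k-fold (default 5) with 1 or 30 repetitions; per fold,
MSE_k = Σ(x_i − x̂_i)²/n_k on 0/1 labels and the CV error is
Σ(n_k/n)·MSE_k — the printed cross-validation formula lacks the 1/n
normalisation and is implemented as this weighted mean, which
reproduces the 8.3% (46/552) and 50% (300/600) base rates of the
all-majority classifier. Metrics are averaged over folds then
repetitions; a pooled mode (metrics over concatenated held-out
predictions) exists, fold-averaging is the default. Sensitivity with no
positive labels is reported as missing, not zero. AUC uses midranks for
ties and equals the trapezoidal ROC area exactly; ROC staircases are
exported at every distinct score threshold. Stratification is on by
default because unstratified 46/552 folds can lose the case class
entirely (a validation error advises enabling it).

## Problem sizes

Cohort-level tests and the acceptance script use the full 506/46 class
structure with 20-minute records and 1 CV repetition, and the
module-level tests use 5–10-minute records — record length and
repetition count scale the computation without changing the class
structure, the feature definitions, or the imbalance phenomenology, and
the generator default remains the clinical 90 minutes. The DFA /
box-dimension oracle checks use 4096-sample series and 100 replicates.

## Known limitations

* The 0.034 Hz cutoff (taken literally from the source) removes most
  of the classical short-term variability band; STV computed after it
  reflects slow-wander and event structure rather than beat-to-beat
  variation. The cutoff is configurable for users who want the
  conventional behaviour.
* Box-counting D on sampled paths retains a small negative bias even
  with the resolution cap.
* SMOTE-before-CV inflates fold metrics (documented in the README;
  within-fold mode provided).
* The synthetic outcome panel's blood-gas fields are plausible but not
  clinically calibrated; only the pH banding is structurally meaningful.
* The WFDB-style reader is a minimal plain-text header+samples format,
  not a binary-format parser.
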