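# ctglearn

Classification of caesarean-section versus normal vaginal deliveries from
intrapartum foetal heart rate (FHR) signals.

Cardiotocography (CTG) traces are read visually by obstetricians and
midwives, with notoriously high inter-observer variability. `ctglearn`
implements an objective alternative for researchers in biomedical signal
processing: it extracts a compact set of clinically grounded and
non-linear features from 4 Hz FHR recordings and trains classifiers to
separate deliveries that ended in caesarean section (cases) from normal
vaginal deliveries (controls), handling the severe class imbalance such
cohorts exhibit (typically ~8% cases).

## What it computes

**Preprocessing.** Signal dropouts (zero-valued runs) are filled with a
monotone cubic Hermite spline; the signal is then low-passed with a
6th-order Butterworth filter at 0.034 Hz applied forward and reverse
(zero phase).

**The 13 features** of a preprocessed signal X = {x_n}:

| family | features |
| --- | --- |
| FIGO morphology | real baseline RBL (mean after clipping excursions to x̄ ± 10 bpm); acceleration/deceleration counts (runs ≥ ±15 bpm from RBL lasting ≥ 15 s); STV (per-minute mean \|S̄_j − S̄_{j+1}\| of 2.5-s epoch means); LTV (mean per-minute max − min) |
| time series | RMS = √(Σx_i²/N); SampEn(m=2, r=0.2·SD) = −ln(A/B), the conditional probability that length-m template matches extend to m+1 (Chebyshev distance, no self-matches) |
| frequency | FPeak — the non-DC peak of the Welch power spectral density (Hamming, 64-s segments, 50% overlap) |
| non-linear | Poincaré SD1 = √(½)·SDSD and SD2 = √(2·SDNN² − ½·SDSD²) of the beat-interval series, and SDRatio = π·SD1·SD2; box-counting dimension D of the signal graph; DFA scaling exponent α |

**Imbalance and selection.** SMOTE grows the minority class along
segments to k = 5 nearest minority neighbours and the majority is
undersampled, to a balanced 300/300 design; recursive feature
elimination ranks features by random-forest importance and keeps the
subset size with the best cross-validated AUC.

**Classifiers.** Fisher's linear discriminant (w ∝ S_W⁻¹(μ₀ − μ₁),
boundary at the projected midpoint of the class means), a random forest
(bootstrapped unpruned trees, √d features per split, majority vote), and
a deep feedforward network (tanh hidden layers, softmax output,
cross-entropy loss, SGD with momentum, learning-rate annealing and
dropout), all behind one `fit`/`predict` contract.

**Evaluation.** Repeated stratified 5-fold cross-validation;
sensitivity, specificity, F-measure; CV error as the fold-size-weighted
MSE on 0/1 labels (equal to the misclassification rate for hard
predictions); AUC by the rank statistic
Â = (S₀ − ½n₁(n₁+1))/(n₁n₂) with midranks for ties.

**Synthetic cohorts.** Because the clinical database cannot be bundled,
`ctglearn.synthetic` generates labelled cohorts with the same structure:
506 controls / 46 cases at 4 Hz, up to 90 min, dropouts, cases with a
flattened, sluggish baseline and frequent deep decelerations, controls
with richer wander and regular accelerations, plus per-record
between-subject heterogeneity so the classes overlap realistically. The
46-case clinical outcome panel (pH, BDecf, pCO2, BE, Apgar) ships as a
packaged fixture, and the pH grouping rule (≤ 7.20 acidosis;
7.20 < pH ≤ 7.25 foetal deterioration; > 7.25 clinical decision)
reproduces its 18/4/24 split.

## Worked example

`examples/05_full_experiment.py` runs the imbalanced and rebalanced
designs on a small synthetic cohort (80 controls / 16 cases, 10-minute
records):

```
original (n=96):
  flda: sens=0.88 spec=0.79 auc=0.903 cv_error=0.198
  rf  : sens=0.62 spec=0.98 auc=0.980 cv_error=0.083
  dl  : sens=0.44 spec=0.90 auc=0.794 cv_error=0.177

smote_all (n=120):
  flda: sens=0.98 spec=0.78 auc=0.927 cv_error=0.117
  rf  : sens=1.00 spec=0.90 auc=0.988 cv_error=0.050
  dl  : sens=0.95 spec=0.75 auc=0.894 cv_error=0.150
```

On the imbalanced cohort the thresholded learners favour the majority
class: specificity is high while case recall (sensitivity) is
suppressed — most visibly for the random forest and the network. After
SMOTE rebalancing, sensitivity rises for every model at a modest cost in
specificity. The other examples (`examples/01`–`04`) walk through
generation/preprocessing, feature extraction, SMOTE and RFE
individually.

A thin command line mirrors the stages:

```sh
ctg synth --controls 506 --cases 46 --duration 90 --seed 7 --out cohort/
ctg features cohort/ features.csv
ctg balance features.csv balanced.csv --minority 300 --majority 300 --seed 7
ctg select balanced.csv rfe.json --folds 5 --seed 7
ctg evaluate balanced.csv report.json --model rf --folds 5 --seed 7
ctg run --config experiment.yml
```

> **Caveat — SMOTE before cross-validation.** The `smote_all` and
> `smote_rfe` designs resample the *whole* dataset before CV, matching
> the classical study design they reproduce. Synthetic neighbours of
> test-fold points then leak into training folds, so fold metrics are
> optimistically biased. For unbiased estimates use
> `smote_within_folds: true` (or pass a `resampler` to
> `cross_validate`), which resamples training folds only.

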