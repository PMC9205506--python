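# Methods

`stepselect` implements a two-stage consensus procedure for deciding which
clinical characteristics matter when predicting whether a chronic stroke
survivor's average daily step count (ASPD) falls below a walking-activity
threshold. Two thresholds are built in: 2500 steps/day (home- versus
community-ambulator) and 5500 steps/day (roughly the level at which aerobic
physical-activity guidelines can be met through walking). This note records
the model, the parameters that matter, the numerical choices, and the
limits of what the synthetic experiments can show.

## Outcome construction and preprocessing

ASPD is the sum of step counts over *valid* wearable recording days divided
by the number of valid days; a participant with no valid day has no defined
outcome and is rejected. What makes a day "valid" is a property of the
device and study protocol, not of this package, so the synthetic generator
parameterizes the invalid-day rate instead of hard-coding a rule. The
binary label is 1 iff ASPD is strictly below the threshold; the
below-threshold group is the target class.

Missingness is handled in a fixed order — features with more than
`max_missing_fraction` (default 5%, strict inequality) missing entries are
removed first, then any participant with a missing value among the retained
features — because that order is what makes reduction counts (features
kept, then participants excluded) well defined.

The design matrix is min-max scaled to [0, 1]. The default fits the scaler
once on the full table *before* splitting. That is a mild information leak:
the test fold's minima and maxima inform the training transform. It is kept
as the default because it reproduces the reference analysis pipeline this
package implements; `scaler_mode="per_fold"` refits the scaler inside every
training fold (implemented by wrapping each estimator in a scikit-learn
`Pipeline`) for leak-free use. Ordinal and categorical variables enter as
their integer codes and are scaled like any other column; one-hot encoding
is deliberately not the default, matching how such cohort tables are
typically coded and analyzed. A constant column scales to 0 everywhere — it
carries no information and this keeps the transform total. Values outside
the fitted range are not clipped.

## Resampling machinery

Both stages score models by Monte-Carlo cross-validation (MCCV): K
independent uniform-random 70/30 train/test partitions (train size =
`round(0.7·n)`), generated once per stage and reused across every model in
that stage so that between-model comparisons are paired. Splits are not
stratified; when labels are supplied, a split whose training set lacks a
class is redrawn (a safeguard that essentially never triggers at realistic
cohort sizes).

Confidence intervals are empirical percentile bootstrap intervals: B
resamples of size m drawn with replacement, the statistic computed on each,
and the 2.5/97.5 empirical percentiles (linear interpolation between order
statistics) of the B statistics taken as the interval. Defaults are
B = 1000, m = 100, level 0.95. The reference procedure's m equals its
K = 100; when a run scales K down, the pipeline therefore scales m with it
(`m=None` tracks K). Holding m at 100 while K shrinks would tighten the
interval relative to the Monte-Carlo noise of the mean and destroy the
null calibration. The bootstrap sorts its input before resampling, making
results invariant to input permutation at a fixed seed.

## Stage 1 — lasso screening

Two L1-penalized linear classifiers are used: logistic regression
(liblinear) and a linear SVM (squared hinge, primal). Regularization
follows scikit-learn's inverse convention: `C` is the inverse penalty
strength. `C` is tuned per family by a grid search with two refinements —
seven log-spaced values over [1e-3, 1e3], then twice seven values spanning
one decade around the incumbent best — scored by mean MCCV metric. Ties go
to the smaller `C`: the purpose of this stage is reduction, so when the
accuracy surface is flat the sparser model wins. If every candidate drives
all coefficients to zero the search fails loudly, naming the grid bounds.

The tuned model is then refitted on each of the K training folds and the K
coefficient vectors per feature form a sample. A percentile bootstrap CI
for the *median* coefficient is computed per feature and per family. A
feature is dropped only when zero lies inside the CI for *both* families.
The intercept is unpenalized and never screened. A fit that has not
converged after one retry at a tenfold iteration cap is flagged and
excluded from the CIs, with the count carried on the result rather than
silently dropped.

On the synthetic cohorts this package generates, the tuned penalty usually
lands on a flat weak-penalty plateau and the screen retains most features
(~16–20 of 25). That is a real property of independent-noise designs: with
every null feature uncorrelated with the rest, weak penalties cost little
test accuracy, and a feature's sampled in-cohort association is picked up
consistently across overlapping splits. Strongly collinear real cohort data
tends to reduce much harder. The screen's guarantees asserted by the test
suite are the ones that hold regardless: planted signals are always kept,
the retained set always shrinks, and the screen collapses to the empty set
in the strong-penalty limit.

## Stage 2 — drop-column importance and consensus

Three deliberately dissimilar classifier families are run with their
library-default hyperparameters: logistic regression, an RBF-kernel SVM,
and a random forest. For each split of a shared plan, a benchmark model is
fitted on all stage-1 survivors and scored on the test fold; for each
feature the model is refitted with that column removed — from both the
train and the test matrix, since prediction requires matching columns — and

    importance = benchmark performance − dropped-column performance.

The benchmark is fitted once per split and reused against every feature's
refit. The forest receives one seed per split, derived from the run seed
and shared between the benchmark fit and every refit within that split, so
importance differences reflect the column and not resampled tree noise.
Folds where the metric is undefined (balanced accuracy with a class absent
from the test fold) are flagged and excluded for all features of that
split, and the count is reported.

A feature is *important to an algorithm* iff the 95% bootstrap CI for its
mean importance is strictly positive (a lower bound of exactly 0 fails).
Features important to all three families are *primary*, to one or two
*ancillary*, to none *unimportant*.

A caution that the test suite measures rather than assumes: the
per-algorithm flag is anti-conservative on null features. MCCV splits of
one dataset overlap, so a noise feature's sampled correlation with the
outcome is present in both the train and test portions of every split; its
within-dataset importance is then genuinely nonzero, and the CI detects it
at rates well above the nominal 2.5% (we measure 15–30% per algorithm on
null cohorts at n = 120–268). What controls false discovery in practice is
the three-family consensus — in particular the forest flags sparingly — and
the suite's null-control check is therefore stated at the consensus level:
a designated null feature essentially never reaches *primary*. Users should
read per-algorithm flags as descriptive, and primary status as the
inferential claim.

## Performance evaluation

Standard accuracy (fraction correct) is the default metric for the 5500
threshold; balanced accuracy ((recall + specificity)/2) for the strongly
imbalanced 2500 threshold. Both are overridable per threshold. The
uninformed baselines are p² + (1−p)² for standard accuracy (random guessing
at the observed class frequencies) and 0.5 for balanced accuracy at any
imbalance. Note that a *fitted* classifier on pure-noise data approaches
the majority rate max(p, 1−p), which exceeds the random-guess baseline
whenever p ≠ ½ — so null-calibration checks for standard accuracy are
meaningful only near even class balance, and the suite runs them there.

Model performance is evaluated over a freshly generated plan (never the
importance plan), for the full feature set and the stage-1 selection, for
all three families. When the class-weight grid is enabled (the default
exactly when the metric is balanced accuracy), each family is evaluated
with `class_weight` None and `"balanced"` over the full plan and the winner
by mean metric is reported. Summaries carry per-split scores plus mean, SD,
min and max, and are rendered in reports as e.g.
`78.6% (SD 4.8%, range 68.7% - 90.1%)`.

A single-predictor precision–recall helper sweeps all unique thresholds of
one continuous measure (negate protective measures so that higher means
positive class), reporting the curve, the average precision, and the
no-skill level (positive prevalence).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular device or population. Features are a mix of continuous
(standard normal, optionally equicorrelated in blocks via a Gaussian
copula), ordinal, and categorical variables stored as integer codes,
mirroring a chronic-stroke assessment battery (walking capacity, balance
confidence, mood, deprivation, comorbidity, demographics). The outcome is
linear-Gaussian on the steps/day scale,

    aspd_true = base + Σⱼ coefⱼ·zⱼ + ε,  ε ~ N(0, σ²), floored at 0,

with zⱼ the standardized feature — linear on the step scale, not logistic
on a label, so both thresholds cut one latent variable, as in the real
analysis. Each participant then gets `wear_days` (default 7) recording
days, each independently invalid with probability `invalid_day_rate`
(default 0.1; at least 3 valid days are forced), valid-day counts normal
around `aspd_true` (day-level SD 800 steps, a realistic within-person
day-to-day spread) rounded and floored at 0, and invalid days carrying junk
counts that the ASPD computation must ignore.

`study_spec` solves the intercept and total latent SD analytically so that
P(ASPD < 2500) = 21.64% and P(ASPD < 5500) = 69.03% — the class
distributions of the n = 268 cohort the analysis is calibrated to — and
this calibration is invariant to how many signals are planted: planted
effects and residual noise always combine to the same total spread. The
default plants two signals (walking endurance and speed modulation) at 1.25
residual-noise SDs per standardized unit each, a strong effect that yields
MCCV balanced accuracies near 0.78, comparable to what such cohorts
support.

What the generator does **not** emulate: device measurement error beyond
symmetric day-level noise, time-series structure in daily steps, the heavy
mutual correlation of real clinical measures (unless blocks are requested),
and covariate distributions fitted to any real cohort. Consequently,
passing tests show the *procedure* behaves correctly (recovery, null
control, calibration, determinism) under a clean data-generating process;
they do not certify accuracy figures for real stroke data.

## Problem sizes and numerical choices

- Reference defaults: K = 100 splits, 70/30, B = 1000, m = 100, 95% CIs,
  5% missingness cutoff, global scaling — `RunConfig()` reproduces these.
- The test suite's replicate experiments run scaled down, chosen to keep
  the full suite in the tens of minutes on one core: the 20-seed recovery
  suite runs n = 500 cohorts at K = 10 (m = 10, 8 tuning splits); the null
  importance study runs 50 cohorts at n = 120, K = 30; the acceptance
  script runs the full pipeline at n = 268, K = 40 (20 tuning splits).
  Split counts enter CI widths through m = K, so these runs are noisier but
  calibrated the same way as the reference configuration.
- Random-forest determinism: per-split seeds derived from the run seed via
  `numpy.random.SeedSequence`; all derived seeds are 31-bit.
- Quantiles use linear interpolation; tie-breaks in tuning go to the
  stronger penalty; label boundaries are strict (ASPD exactly at a
  threshold is above it; a CI lower bound of exactly 0 is not positive).

## Known limitations

- Per-algorithm importance flags are anti-conservative on null features
  (measured above); treat only consensus-primary status as inferential.
- The global min-max scaler leaks fold information by design (faithfulness
  default); use `per_fold` mode for honest error estimates on new data.
- Lasso screening keeps most features when predictors are mutually
  independent; its reduction power depends on collinearity structure.
- Balanced accuracy is undefined on test folds missing a class; such folds
  are excluded with a reported count, which slightly biases scores when
  they occur (they essentially never do at n ≥ 100 with 70/30 splits).
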