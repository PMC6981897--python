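# Methods

## Scope and model

`hrmets` re-creates, on synthetic cohorts, a pooled-regression approach to
estimating the metabolic intensity of daily activities from heart rate
without per-person calibration. The quantity estimated is the MET — the
ratio of an activity's energy expenditure (EE) to seated resting EE, both
obtained from expired-gas indirect calorimetry through the abbreviated Weir
equation EE = 3.941·V̇O₂ + 1.106·V̇CO₂ kcal/min (protein oxidation ignored;
the constants are the standard abbreviated form). The predictor of interest
is percent heart-rate reserve,

    %HRR = (HR − HR_rest) / (HR_max − HR_rest) × 100,

with HR_max predicted from age by the Tanaka equation 208 − 0.7·age
(validated for adults; inputs outside 18–80 y are rejected). %HRR is never
clamped: group means near 0 % with SDs of 3–4 % imply that mildly negative
individual values occur at seated tasks and must be retained.

The statistical model is ordinary least squares on pooled subject-activity
observations,

    METs_ij = β₀ + β₁·%HRR_ij + γ'·z_i + ε_ij,

where z_i are per-subject covariates (resting HR, sex, age, height, weight
or BMI). Model development enumerates *all* covariate subsets (the HR
variable — absolute HR or %HRR, never both, r ≈ 0.93 between them — is
structural in every candidate), in two families that keep BMI apart from
its components: family A allows {age, height, resting HR, sex, weight}
(2⁵ = 32 candidates), family B {age, BMI, resting HR, sex} (2⁴ = 16).
Candidates are screened for sign consistency (each coefficient's sign must
match the predictor's marginal Pearson correlation with METs; zero on either
side passes) and for collinearity (VIF from auxiliary regressions; ≥ 10
excludes, ≥ 1.1 is flagged for report only — the original analysis observed
all VIFs under 1.1 but never stated an exclusion rule). The minimum-AIC
survivor wins; ties break toward fewer predictors, then lexicographic
predictor names.

### AIC variant

We use the Gaussian profile-likelihood form AIC = n·ln(RSS/n) + 2(k + 2),
counting k slopes, the intercept and the error variance. The full-likelihood
form (adding n·ln 2π + n) is provided as `aic_gaussian` and is
rank-equivalent; the tests assert identical orderings. Absolute AIC values
are therefore not comparable across software, rankings are. A zero RSS makes
AIC −∞; selection then falls back to the fewest-predictors tie-break.

## R-R preprocessing

Beat-to-beat R-R recordings are resampled onto fixed 0.4-s epochs; an
epoch's HR is 60 divided by the overlap-weighted mean R-R of the beats
covering it (weighting by overlap was chosen over nearest-beat assignment
and is verified against a brute-force beat-iteration oracle). Epochs with no
beat coverage are missing. Outliers are screened in a single pass over the
whole recording: epochs outside mean ± k·SD become missing, k = 4 for radio
calisthenics (a jumpy whole-body routine producing legitimately wide swings)
and k = 3 otherwise. A constant trace (SD = 0) removes nothing. The activity
HR is the unweighted mean of per-minute means; minutes whose epochs are all
missing are dropped, and a trailing partial minute enters only with ≥ 15 s
of non-missing coverage. Resting HR applies the same minute averaging to a
7-min seated window. Open choices here (single-pass vs iterative screening,
the 15-s partial-minute rule) are deliberate: the protocol descriptions this
emulates do not specify them, and the simplest consistent reading was taken
and oracle-tested.

## The synthetic cohort generator

The generator is the package's stand-in for the undisclosed study data and
defines the conditions every downstream check runs under.

**Subjects.** Four 10-year age decades (20s–50s) × two sexes, 4–6 subjects
per cell, 20 per sex (40 total by default). Age, height, weight and resting
HR are drawn from per-cell Gaussians at the published cell means/SDs,
truncated at ±3 SD (ages additionally clipped to their decade) to exclude
impossible anthropometrics. BMI and predicted HR_max are derived, never
drawn. Within a cell, traits are drawn independently; the published VIFs
(< 1.1) indicate the real cohort was close to this.

**Observations.** Each of the 20 catalog activities carries a target %HRR
mean/SD, a MET mean/SD, a usable-N count and a screening k. Per retained
subject-activity pair: %HRR ~ N(activity mean, SD) truncated below at −5 %
(heart rates meaningfully below resting do not occur in task data); the
absolute HR is back-computed from the subject's *own* resting HR and
predicted HR_max, guaranteeing internal consistency; METs = linear truth +
N(0, residual SD). The default truth is the published three-predictor
equation (intercept −0.176; 0.106 per %HRR point; −0.017 per bpm resting
HR; 0.014 per cm height; sex effect 0, as sex is absent from that model)
with residual SD 0.623 METs, its published SEE. A single-predictor truth
(1.053 + 0.105·%HRR, SD 0.648) is used for the SEE-recovery and
limits-of-agreement studies.

The residual is an *untruncated* Gaussian. At the default SD, roughly 0.4 %
of draws in the two lowest-intensity activities (~1.1 METs) come out
non-positive; truncating or redrawing them measurably attenuates recovered
coefficients and SEE, so positivity is not enforced at generation. Percent
error is undefined for a non-positive measured value, so `activity_report`
excludes such pairs from the MPE columns only (flagged, retained for RMSE
and the signed-rank test).

**Missingness.** `missing_pattern="table2"` drops subjects uniformly at
random per activity down to the published usable-N column (673 pooled
observations for 40 subjects); the study does not say which recordings
failed, so uniform dropout is the neutral choice. `"none"` keeps the full
800-row grid.

**Calibration.** The analytic population R² of the generator —
Var(linear predictor)/(Var + SD²) with predictor variances computed from the
configured mixtures (activity Gaussians weighted by usable N or uniformly,
cell mixtures for resting HR and height, Bernoulli(½) sex) — lands within
0.02 of the published R² for both default truths with no tuning. A
calibrated mode rescales linear-predictor deviations around the analytic
mean to hit a user-supplied target R² exactly in expectation, used by the
fit-statistic recovery tests since the real predictor covariances are
unknown.

**R-R emulation.** Synthetic beat series fluctuate multiplicatively
(default CV 3 %, a realistic short-term HRV magnitude for task-level
recordings) around 60/target-HR, with artifacts at a configurable per-beat
rate: half dropouts (a missed QRS doubling the interval), half spurious
detections (a split interval). This emulates patch-ECG failure modes well
enough to exercise the ±k SD screen; it does not model HR on-kinetics,
drift, respiratory sinus arrhythmia spectra or circadian effects.

All generator outputs are pure functions of (configuration, seed).

## Validation machinery

Cross-validation is at the **subject** level throughout: a subject's 20
activities leave the development set together, since resting HR, height and
sex repeat across a subject's rows and observation-level folds would leak
them. Leave-one-subject-out refits the candidate once per subject and
predicts each observation exactly once. Repeated hold-out splits subjects
2:1 (development = round(2n/3)), refits, scores per-activity RMSE on the
validation group, and averages over repetitions; an activity absent from a
split's validation side simply contributes nothing to that repetition. The
full protocol specifies 10,000 repetitions; the drivers and tests use 500,
which two independent runs show agrees per activity to well under 0.02 METs.

Error summaries: MPE = (estimated − measured)/measured × 100, aggregated as
mean ± SD over the pooled leave-out predictions per activity (the reading
consistent with published per-activity SDs); RMSE per activity; two-sided
Wilcoxon signed-rank per activity (exact null distribution up to 25 non-zero
differences, normal approximation above). Agreement uses the modified
Bland–Altman form: differences (estimated − measured) are summarised as
bias ± 1.96·SD (95 % limits of agreement) and correlated against *measured*
METs — the reference method — rather than the pair mean; the classic
mean-axis form is available via an argument.

## Numerical and degenerate-input conventions

- OLS needs n ≥ k + 2 (one residual degree of freedom, so SEE =
  √(RSS/(n−k−1)) is defined); rank-deficient designs are rejected naming an
  offending predictor.
- Standardized β = coefficient × SD(x)/SD(y), sample SDs with ddof = 1.
- Single-predictor VIF is exactly 1; auxiliary-regression VIF otherwise.
- Epoch screening with all-missing input, minute averaging with no usable
  minute, Bland–Altman with < 3 pairs, MPE with non-positive measured
  values: all rejected or flagged rather than silently propagated.

## What passing tests do and do not show

The generator reproduces the published design's *first-order structure*:
strata, activity distributions, missingness counts, and a MET response
linear in the published predictors with homoscedastic Gaussian residuals.
Consequences to keep in mind:

- **Per-activity RMSE is flat** (~the residual SD everywhere). The original
  study saw RMSE grow with intensity — heteroscedasticity of real
  calorimetry data the generator deliberately omits. Recovery tests assert
  the flatness the generator implies, not the trend it cannot produce.
- **Percent errors at ~1-MET activities are huge** under a constant 0.62-MET
  residual SD, so total MPE ± SD is not comparable to the published ±22 %;
  RMSE and limits of agreement are the comparable quantities.
- **VIF on replicate cohorts is noisy.** The VIF between resting HR and
  height has an effective sample of 40 subjects; even under exact
  population independence the subject-level sample correlation
  (≈ N(0, 1/√37)) pushes ~8 % of cohorts above the 1.1 flag, and the
  maximum over 20 replicate cohorts typically lands near 1.15. The
  published < 1.1 is a single-realization observation, not a property the
  design can guarantee.
- True predictor correlations, HR dynamics within activities, and
  repeated-measures error correlation within subject (noted as an
  overfitting risk in the original analysis) are not modelled.

## Problem sizes used

Recovery studies average 100 replicate cohorts (coefficients, SEE), 50
(limits of agreement, modal rounding) or 20 (VIF), each a full 40-subject /
673-observation regeneration — sizes at which Monte-Carlo standard errors
are an order of magnitude below the effects being checked. Hold-out uses
500 repetitions as its converged desk-scale default.
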