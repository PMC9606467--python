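# Methods

## The analysis chain

The package reproduces a standard ambulatory-ECG analysis design: a
multi-day chest-patch recording (nominally Thursday 09:00 to Monday
17:00, 104 h) yields beat annotations and acceleration magnitudes;
windowed features are quality-filtered and aggregated to hourly
records; circadian structure, night-time vagal tone and acute stress
reactivity are then modelled with linear mixed models over
depression/chronic-stress groups.

### Windowing and quality rules

Windows are 300 s advanced by 60 s (4 min overlap), assigned to the
wall-clock hour of their *start*. The signal-quality index follows the
rule-based tradition for ambulatory ECG: the window is split into 10-s
sub-segments and each must satisfy (defaults, all configurable) implied
HR within 40–180 bpm, no RR interval above 3 s, max(RR)/min(RR) ≤ 2.2
and mean beat-morphology correlation ≥ 0.66; the QI is the passing
fraction. Exclusion boundaries are strict: QI = 0.8 and
Std Acc = 0.04 g are *retained* (the rules exclude "below 0.8" and
"above 0.04"). Std Acc uses the population SD (the N vs N−1 distinction
is negligible at 32 Hz × 300 s but is fixed for reproducibility).
Hourly records require ≥ 5 retained windows; circadian modelling
requires all 24 clock hours to appear at least once across the whole
recording, with no within-day consecutiveness constraint. Night-time
records are the hours 22:00–05:00, re-indexed time = 1…8.

### Mixed models

All three models share one random-effects structure family: a
per-subject random intercept plus *independent* random slopes
(diagonal covariance). For the circadian model the slopes are the 8
harmonic columns; for the night model, the linear time index; the
reactivity model has the intercept only. A full unstructured 9×9
random-effect covariance is not estimable at these design sizes, and
the diagonal choice is declared rather than silently approximated.

The fitter (`circastress.lmm`) profiles the likelihood: with variance
ratios θ_k = σ_k²/σ², the per-subject marginal covariance is
V_i = I + Z_i diag(θ) Z_i', and both the GLS fixed effects and σ² are
closed-form given θ. All required quantities reduce to q×q operations
on precomputed per-subject cross-products (Woodbury identity), and the
optimiser searches only over log θ with the analytic gradient of the
profiled ML/REML deviance (L-BFGS-B, bounds log θ ∈ [−16, 8]; a ratio
pinned at the lower bound flags the fit *singular*). Agreement with
statsmodels' MixedLM — an independent implementation — is enforced in
the test suite to ~1e-5 on coefficients, standard errors, variance
components and log-likelihoods. Convergence is reported honestly: the
optimiser's own success flag, or a vanishing *projected* gradient.

Wald t/z statistics use the large-sample normal approximation (the
reference analysis stack does not fix a degrees-of-freedom method;
normal is the declared choice here). Joint ("type-3") factor tests are
Wald F-tests with denominator df n − p. Conditional R² is the
fixed-plus-random share of total variance on the log (link) scale.

Model selection uses ML (AIC across fixed-effect structures is a
likelihood comparison), the reported final fit REML. Backward
elimination removes, per round, the term whose removal lowers AIC most,
under marginality (no main effect leaves while a retained interaction
contains it; a sine/cosine pair of one period moves as a unit), and
stops when no removal improves AIC; on small model spaces this is
verified against exhaustive subset enumeration. Split-by-stratum
circadian fits are *not* stepwise-selected by default: recovery of
planted effects over replicates would otherwise be distorted by
selection (coefficients conditioned on retention are biased away from
zero), so the split models estimate the declared full specification.

Numerical covariates (age, BMI, hourly activity index) are min-max
rescaled to [0, 1] over the data entering the model; BMI is
median-imputed first. A covariate that is constant within an analysis
subset (e.g. no smokers in a small stratum) is dropped with a warning —
it is aliased with the intercept. A factor level absent from a stratum
is an error (the contrast is inestimable), deliberately not papered
over.

### Contrasts

Within a stratum of one grouping factor, the 6 pairwise condition
differences of the stress task are linear combinations of the fitted
coefficients. The factor *not* stratified on is averaged over using its
observed proportions by default ("proportional"); this choice, rather
than equal weighting, makes the stratum contrasts consistent with the
companion coefficient estimates (equal weighting is available as an
option). The 6 p-values of one stratum form one Benjamini–Hochberg
family; pooling both strata into one family is a caller-side choice.

## The synthetic cohort

The generator emulates a healthy working cohort of 516 adults: age and
BMI from truncated normals whose underlying parameters are solved so
the *truncated* moments hit the configured targets (mean 39.44/SD 10.21
years; 24.20/3.78 kg/m²), 47% women, ~7% smokers, five weekly-sport
categories. PSS-10 is a truncated (0–40) rounded normal (14.21/6.01) —
its 75th/95th percentiles land at the fixed cuts 18/24 — and the DASS
depression score a negative binomial truncated to 0–21 with dispersion
derived from mean 2.50/SD 2.91, giving the right-skewed, heavy-tailed
shape (skewness ≈ 2) typical of depression scores in non-clinical
samples. Optional group-share overrides assign groups first and draw
scores from within the matching band; studies with enriched rare arms
(extreme stress, high depression) are simulated this way.

Hourly log HR follows the circadian mixed model exactly: intercept,
8 harmonic terms (default amplitudes place the trough near 02:30 and
the peak early afternoon, total swing ≈ ±10%), covariate effects on the
rescaled scale, group effects, N(0, 0.10) random intercepts,
N(0, 0.02) harmonic random slopes and N(0, 0.05) residuals — SDs chosen
so the between/within split yields a conditional R² near 0.75. The
planted group effects are the published point estimates: +0.031 basal
log-HR for high chronic stress without depressive symptoms; −0.084
basal shift, +0.022 × sin(2πt/12) and +0.011 × cos(2πt/8) for extreme
chronic stress with depressive symptoms. With every SD set to zero the
series equals the deterministic planted curve and all downstream fits
recover the coefficients to numerical precision — the package's primary
correctness argument.

The intercept is calibrated analytically (lognormal mean corrections
over the harmonic/random-effect/residual structure) so the cohort
grand-mean HR hits a configurable target, 67.87 bpm by default.
Missingness drops hours independently at 0.194, reproducing the ~84
valid hourly averages per participant of a realistic 104-h recording.

Night-time log RMSSD gets its own planted model (intercept 3.90 ≈
49 ms; strong negative rescaled-age effect; group effects +0.088
depression, +0.041/+0.177 high/extreme stress, −0.099/−0.210
interactions; +0.015/h night slope with small negative group
interactions; random intercept SD 0.30, time-slope SD 0.02, residual
0.20 — RMSSD is noisier than HR). Daytime RMSSD values are plausible
filler only and are never modelled.

The stress task plants the 12 published fixed effects of the
reactivity model (intercept 4.239; condition effects 0.006/0.028/0.0003
for training/stress/recovery; −0.037 stress × depression; +0.025
stress × chronic stress; …) at the minute level, with random-intercept
SD 0.13 and minute-residual SD 0.10 back-solved from the published
standard errors. Because the analysis chain averages HR on the bpm
scale within a condition and then log-transforms, minute-level noise
would shift the fitted intercept by a Jensen offset
(≈ σ²/2·(1−1/k) ≈ 0.004); the generator subtracts this analytically so
the planted intercept is the estimand of the fitted model. The offset
cancels in every non-intercept coefficient and vanishes with zero
noise.

Beat-level streams exist for validating the pre-processing chain: RR =
60000/HR(t) plus white jitter of SD target_RMSSD/√2 (white jitter of SD
s has RMSSD s√2), morphology correlations ~U(0.85, 1) when clean;
artifact segments get implausible RR and morphology < 0.4, activity
bursts elevated acceleration variance and HR. Acceleration is 1 g
baseline with 0.012 g SD (quiet) vs 0.2 g (bursts).

Every participant draws from `SeedSequence([seed, index, stage])`:
identical seeds give byte-identical output, and enlarging a cohort
never reshuffles existing participants.

### What the generator does *not* emulate

Real ambulatory data have autocorrelated residuals, posture/sleep-stage
structure, correlated random effects, informative missingness (device
removal during exercise), and questionnaire measurement error. Passing
recovery tests therefore demonstrates the *correctness of the
estimation machinery under the declared model*, not robustness to those
violations; the quality-filter chain is exercised on stylised artifact
and activity-burst patterns rather than recorded noise.

## Problem sizes and replication

Replicate studies use 100 stress-task cohorts at the study's group
sizes (194; 180/14; 152/42) and 50 hourly cohorts of n = 200 with
enriched group shares (30% high depression; 40/30/30 stress) so the
rare extreme-stress × depression cell (~18 subjects) is estimable;
recovery is judged against the planted value within 2 Monte-Carlo
standard errors of the replicate mean. The calibration check uses the
full default cohort (n = 516). These sizes keep a complete validation
run in the minutes range on a single CPU while leaving Monte-Carlo
error well below the effect sizes of interest.

## Known limitations

- The random-effect covariance is diagonal by design; analyses of data
  generated with strongly correlated intercepts/slopes will misstate
  variance components (fixed effects remain consistent).
- Satterthwaite/Kenward-Roger df are not implemented; p-values are
  anti-conservative in very small strata.
- The stepwise trace records eliminations only; it does not explore
  re-additions (pure backward, matching the declared procedure).
- Percentile-based stress cuts are unstable below ~20 subjects (a
  warning is issued); fixed cuts are recommended for small cohorts.
- The QI reimplements the published rule family; the original study's
  exact sub-segment accounting is not recoverable from public sources,
  so thresholds and segment length are configurable.
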