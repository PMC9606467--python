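# circastress

Modelling how chronic stress and depressive symptoms shape the circadian
rhythm of heart rate, night-time vagal tone and acute stress reactivity
in ambulatory ECG cohorts.

The package is aimed at researchers analysing multi-day wearable ECG
studies of working populations: it covers the full chain from beat
annotations to fitted mixed models, and ships a synthetic cohort
generator with *planted*, exactly recoverable ground truth, so every
stage of the pipeline can be validated end to end without access to any
participant data.

## What it computes

**Pre-processing.** Beat streams (RR intervals + per-beat morphology
correlation) and accelerometer magnitudes are cut into 5-min windows
with 4 min of overlap. Each window gets mean HR (beat-wise mean of
60000/RR), RMSSD, the SD of acceleration magnitude (Std Acc) and a
rule-based signal-quality index (QI: fraction of 10-s sub-segments with
physiological HR, no long RR gaps, bounded max/min RR ratio and high
morphology correlation). Windows with QI < 0.8 or Std Acc > 0.04 g are
excluded; survivors are averaged into hourly records (kept when backed
by ≥ 5 windows), and participants must cover all 24 clock hours.

**Circadian model.** Log hourly HR is fitted with a harmonic (cosinor)
linear mixed model,

```
log HR_it = β0 + Σ_p [ a_p sin(2πt/p) + b_p cos(2πt/p) ]  (p = 24, 12, 8, 6 h)
          + covariates + stress/depression groups + group × harmonic terms
          + u_i + Σ_p v_ip·(harmonics) + ε_it
```

with a per-subject random intercept and independent random slopes for
all 8 harmonic terms, AIC backward selection (harmonic sine/cosine pairs
move jointly; marginality respected), and split-by-depression-stratum
fits. Night-time log RMSSD (22:00–05:00, time index 1–8) uses a linear
time trend with the full depression × chronic-stress factorial; the
stress-task model regresses log per-condition HR on group × condition
terms with Benjamini–Hochberg-corrected pairwise condition contrasts.

Groups: DASS depression subscale > 6 → high depressive symptoms; PSS-10
≤ 18 / ≤ 24 / > 24 → normative / high / extreme chronic stress (cuts
either fixed or cohort percentiles).

## Worked example

```python
from circastress import (CohortConfig, generate_profiles,
                         generate_hourly_cohort, fit_circadian_split)

cfg = CohortConfig(n_participants=200, dep_high_prob=0.3,
                   stress_group_probs=(0.4, 0.3, 0.3))
profiles = generate_profiles(cfg, seed=1)
hourly = generate_hourly_cohort(profiles, seed=1)   # planted default effects
res = fit_circadian_split(hourly, profiles, stratum="high")
print(res.params[["stress[extreme]", "stress[extreme]:sin12",
                  "stress[extreme]:cos8"]].round(4))
```

prints

```
stress[extreme]          -0.0543
stress[extreme]:sin12     0.0277
stress[extreme]:cos8      0.0045
```

— the fitted basal log-HR shift for extreme chronic stress within the
high-depressive-symptom stratum and its two circadian interactions, one
replicate's noisy estimates of the planted values (−0.084, 0.022,
0.011): with depressive symptoms present, extreme stress lowers basal
HR and blunts the evening peak. `res.summary()` gives the full
coefficient table, variance components, AIC and conditional R²;
`res.simulate_curves()` returns the group-level 24-h curves with
covariates zeroed.

The same objects exist for the night-RMSSD model (`fit_night_rmssd`)
and the stress task (`fit_reactivity`, whose results expose
`pairwise_contrasts`). A `circastress` CLI orchestrates
simulate → group → fit over a YAML config.

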