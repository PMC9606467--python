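"""Synthetic physiology: hourly series, beat streams and stress-task data.

Three generators, all with planted, recoverable ground truth:

``generate_hourly_cohort``
    The fast path.  Emits per-participant hourly records directly (mean
    HR, night-time RMSSD, activity index, window counts), skipping the
    beat level.  log HR follows the circadian mixed model: intercept +
    8 harmonic terms + rescaled covariates + depression/chronic-stress
    group effects + subject random intercept and harmonic slopes +
    residual noise.  With every SD at zero the output equals the
    deterministic planted curve exactly.

``generate_beat_stream``
    Beat-level fixtures for the pre-processing chain: an RR series
    realising a prescribed heart-rate trajectory plus white jitter whose
    SD is target_rmssd / sqrt(2) (white jitter of SD s has RMSSD
    s*sqrt(2)), with optional artifact segments (low morphology
    correlation, implausible RR) and activity bursts (elevated
    acceleration variance and HR).

``generate_mist_session``
    Per-minute heart rate over the 4 x 5-min stress-task schedule
    (baseline, training, stress, recovery), following the planted
    reactivity fixed effects plus a subject random intercept.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .cohort import generate_profiles, participant_rng
from .config import (
    HARMONIC_NAMES,
    CohortConfig,
    MIST_CONDITIONS,
    PlantedEffects,
    RecordingSchedule,
)
from .groups import dep_group, minmax_rescale, pss_group
from .harmonics import harmonic_design
from .windows import NIGHT_HOURS, AccTrace, BeatStream

__all__ = [
    "generate_hourly_cohort",
    "generate_hourly_series",
    "generate_beat_stream",
    "generate_mist_session",
    "generate_mist_cohort",
    "mist_study_profiles",
    "aggregate_mist",
    "planted_curve",
]

_NIGHT_TIME = {h: i + 1 for i, h in enumerate(NIGHT_HOURS)}


def _rescale_quiet(values: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return minmax_rescale(values)


def _profile_covariates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Median-impute BMI and min-max rescale the numeric covariates."""
    bmi = profiles["bmi"].to_numpy(dtype=float)
    if np.isnan(bmi).any():
        if np.isnan(bmi).all():
            bmi = np.zeros_like(bmi)
        else:
            bmi = np.where(np.isnan(bmi), np.nanmedian(bmi), bmi)
    return pd.DataFrame(
        {
            "pid": profiles["pid"],
            "age_r": _rescale_quiet(profiles["age"].to_numpy(dtype=float)),
            "bmi_r": _rescale_quiet(bmi),
            "female": (profiles["sex"] == "female").astype(float),
            "smoking": profiles["smoking"].astype(float),
        }
    )


def _group_labels(profiles: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    dep = dep_group(profiles["dassd"].to_numpy())
    stress, _ = pss_group(profiles["pss"].to_numpy(), mode="fixed")
    return dep, stress


def planted_curve(effects: PlantedEffects, dep: str, stress: str,
                  hours: np.ndarray) -> np.ndarray:
    """Deterministic group-level log-HR curve (harmonic + group terms only).

    This is the generator's own reference trajectory used to validate
    model-based curve simulation: intercept + harmonics + group shifts +
    the depression-conditional circadian interactions, with covariates
    at zero.
    """
    basis = harmonic_design(hours)
    eta = np.full(len(basis), effects.beta0, dtype=float)
    for name in HARMONIC_NAMES:
        eta += effects.harmonic_betas[name] * basis[name].to_numpy()
    if dep == "high":
        eta += effects.dep_main
    if stress != "normative":
        eta += effects.stress_main.get(stress, 0.0)
        if dep == "high":
            eta += effects.dep_stress_main.get(stress, 0.0)
    if dep == "high":
        for key, beta in effects.dep_stress_circadian.items():
            level, term = key.split(":")
            if level == stress:
                eta += beta * basis[term].to_numpy()
    return eta


def _linear_predictor_hr(effects, basis, cov_row, act_r, dep, stress):
    eta = np.zeros(len(basis), dtype=float)
    for name in HARMONIC_NAMES:
        eta += effects.harmonic_betas[name] * basis[name].to_numpy()
    cb = effects.covariate_betas
    eta += (
        cb.get("age", 0.0) * cov_row["age_r"]
        + cb.get("bmi", 0.0) * cov_row["bmi_r"]
        + cb.get("sex_female", 0.0) * cov_row["female"]
        + cb.get("smoking", 0.0) * cov_row["smoking"]
    )
    eta += cb.get("activity", 0.0) * act_r
    if dep == "high":
        eta += effects.dep_main
    if stress != "normative":
        eta += effects.stress_main.get(stress, 0.0)
        if dep == "high":
            eta += effects.dep_stress_main.get(stress, 0.0)
    if dep == "high":
        for key, beta in effects.dep_stress_circadian.items():
            level, term = key.split(":")
            if level == stress:
                eta += beta * basis[term].to_numpy()
    return eta


def generate_hourly_cohort(
    profiles: pd.DataFrame,
    effects: PlantedEffects | None = None,
    schedule: RecordingSchedule | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Hourly physiology for a whole cohort (the fast simulation path).

    Returns columns pid, clock_hour, hour_of_day, mean_hr, mean_rmssd,
    activity_index, n_windows.  Hours are dropped independently with the
    schedule's missingness probability, emulating quality-filtered
    ambulatory yield (~84 of 104 hours).  When ``target_mean_hr`` is set
    on the effects, the intercept is calibrated analytically (lognormal
    mean corrections included) so the cohort grand-mean HR hits the
    target.
    """
    effects = effects or PlantedEffects()
    schedule = schedule or RecordingSchedule()
    n = len(profiles)
    columns = ["pid", "clock_hour", "hour_of_day", "mean_hr", "mean_rmssd",
               "activity_index", "n_windows"]
    if n == 0:
        return pd.DataFrame(columns=columns)
    H = schedule.duration_hours
    start = pd.Timestamp(schedule.start)
    hours_abs = np.arange(H)
    hod = (start.hour + hours_abs) % 24
    basis = harmonic_design(hod)
    Zh = basis.to_numpy()
    cov = _profile_covariates(profiles)
    dep, stress = _group_labels(profiles)

    # pass 1: per-participant random draws (fixed layout => deterministic)
    act_raw = np.empty((n, H))
    keep = np.empty((n, H), dtype=bool)
    b0 = np.empty(n)
    bsl = np.empty((n, 8))
    eps = np.empty((n, H))
    nwin = np.empty((n, H), dtype=int)
    rb0 = np.empty(n)
    rb1 = np.empty(n)
    reps = np.empty((n, H))
    day = ((hod >= 7) & (hod <= 22)).astype(float)
    sds = np.array([effects.rslope_sds[k] for k in HARMONIC_NAMES])
    for i in range(n):
        rng = participant_rng(seed, i, stage=1)
        b0[i] = rng.normal(0.0, effects.ri_sd) if effects.ri_sd else 0.0
        bsl[i] = rng.normal(0.0, 1.0, 8) * sds
        eps[i] = rng.normal(0.0, 1.0, H) * effects.resid_sd
        base = 0.008 + 0.014 * day
        act_raw[i] = np.clip(base * rng.gamma(4.0, 0.25, H), 1e-4, 0.04)
        keep[i] = rng.uniform(size=H) >= schedule.hour_missing_prob
        nwin[i] = rng.integers(5, 57, H)
        rb0[i] = rng.normal(0.0, effects.rmssd_ri_sd) if effects.rmssd_ri_sd else 0.0
        rb1[i] = rng.normal(0.0, effects.rmssd_time_sd) if effects.rmssd_time_sd else 0.0
        reps[i] = rng.normal(0.0, 1.0, H) * effects.rmssd_resid_sd

    # pass 2: cohort-wide rescaling, calibration and assembly
    act_r = _rescale_quiet(act_raw.ravel()).reshape(n, H)
    night_mask = np.isin(hod, NIGHT_HOURS)
    act_night_r = np.zeros((n, H))
    act_night_r[:, night_mask] = _rescale_quiet(
        act_raw[:, night_mask].ravel()
    ).reshape(n, night_mask.sum())

    eta_star = np.empty((n, H))
    for i in range(n):
        eta_star[i] = _linear_predictor_hr(
            effects, basis, cov.iloc[i], act_r[i], dep[i], stress[i]
        )
    if effects.target_mean_hr is not None:
        var_t = effects.ri_sd**2 + (Zh**2) @ (sds**2) + effects.resid_sd**2
        log_mean = np.log(np.mean(np.exp(eta_star + 0.5 * var_t[None, :])))
        beta0 = np.log(effects.target_mean_hr) - log_mean
    else:
        beta0 = effects.beta0
    log_hr = beta0 + eta_star + b0[:, None] + bsl @ Zh.T + eps

    # night-time log RMSSD model; daytime values are plausible filler
    g = effects.rmssd_night_betas
    time_idx = np.array([_NIGHT_TIME.get(h, 0) for h in hod], dtype=float)
    log_rmssd = np.empty((n, H))
    for i in range(n):
        d = 1.0 if dep[i] == "high" else 0.0
        sh = 1.0 if stress[i] == "high" else 0.0
        se = 1.0 if stress[i] == "extreme" else 0.0
        inter = (
            g["intercept"]
            + g["age"] * cov.iloc[i]["age_r"]
            + g["bmi"] * cov.iloc[i]["bmi_r"]
            + g["sex_female"] * cov.iloc[i]["female"]
            + g["smoking"] * cov.iloc[i]["smoking"]
            + g["dep_high"] * d
            + g["stress_high"] * sh
            + g["stress_extreme"] * se
            + g["dep_high:stress_high"] * d * sh
            + g["dep_high:stress_extreme"] * d * se
        )
        slope = (
            g["time"]
            + g["time:dep_high"] * d
            + g["time:stress_high"] * sh
            + g["time:stress_extreme"] * se
            + g["time:dep_high:stress_high"] * d * sh
            + g["time:dep_high:stress_extreme"] * d * se
        )
        lp = inter + g["activity"] * act_night_r[i] + (slope + rb1[i]) * time_idx
        lp = lp + rb0[i] + reps[i]
        day_fill = g["intercept"] - 0.2 + rb0[i] + reps[i]
        log_rmssd[i] = np.where(night_mask, lp, day_fill)

    frames = []
    stamps = start + pd.to_timedelta(hours_abs, unit="h")
    pids = profiles["pid"].to_numpy()
    for i in range(n):
        sel = keep[i]
        frames.append(
            pd.DataFrame(
                {
                    "pid": pids[i],
                    "clock_hour": stamps[sel],
                    "hour_of_day": hod[sel],
                    "mean_hr": np.exp(log_hr[i, sel]),
                    "mean_rmssd": np.exp(log_rmssd[i, sel]),
                    "activity_index": act_raw[i, sel],
                    "n_windows": nwin[i, sel],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_hourly_series(
    profile: pd.Series | dict,
    effects: PlantedEffects | None = None,
    schedule: RecordingSchedule | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Hourly records for a single participant (cohort path of size 1).

    Covariate rescaling is degenerate for one subject (all zeros), so
    the emitted series reflects intercept + harmonics + group terms +
    that subject's random effects and noise.
    """
    profiles = pd.DataFrame([dict(profile)])
    return generate_hourly_cohort(profiles, effects, schedule, seed=seed)


def generate_beat_stream(
    pid: str = "p00000",
    duration_h: float = 1.0,
    corruption: list[tuple[float, float, str]] | None = None,
    target_rmssd: float = 40.0,
    seed: int = 0,
    mean_hr: float = 70.0,
    hr_trajectory=None,
    acc_rate_hz: float = 32.0,
    start_time: str | pd.Timestamp = "2019-09-05 09:00",
) -> tuple[BeatStream, AccTrace]:
    """Beat annotations plus an accelerometer trace with known corruption.

    ``corruption`` is a list of (start_s, end_s, kind) with kind
    'artifact' (beats get implausible RR and low morphology correlation)
    or 'activity' (acceleration variance and heart rate elevated);
    segments must not overlap.  ``hr_trajectory`` optionally maps time in
    seconds to instantaneous HR (bpm); default is constant ``mean_hr``.
    ``target_rmssd`` = 0 yields a perfectly regular RR series.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    corruption = sorted(corruption or [], key=lambda s: s[0])
    for (a0, a1, _), (b0_, _, _) in zip(corruption, corruption[1:]):
        if b0_ < a1:
            raise ValueError("corruption segments must not overlap")
    for s0, s1, kind in corruption:
        if not 0 <= s0 < s1:
            raise ValueError("corruption segments need 0 <= start < end")
        if kind not in ("artifact", "activity"):
            raise ValueError(f"unknown corruption kind {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    total_s = duration_h * 3600.0
    hr_fun = hr_trajectory or (lambda t: np.full_like(np.asarray(t, float), mean_hr))
    jitter_sd = target_rmssd / np.sqrt(2.0)

    n_est = int(total_s * (mean_hr * 2.5) / 60.0) + 16
    t_ms_list, rr_list = [], []
    t = 0.0
    hr_now = float(np.atleast_1d(hr_fun(0.0))[0])
    jit = rng.normal(0.0, jitter_sd, n_est) if jitter_sd > 0 else np.zeros(n_est)
    k = 0
    while t < total_s * 1000.0 and k < n_est:
        hr_now = float(np.atleast_1d(hr_fun(t / 1000.0))[0])
        for s0, s1, kind in corruption:
            if kind == "activity" and s0 * 1000.0 <= t < s1 * 1000.0:
                hr_now *= 1.35
        rr = max(60000.0 / hr_now + jit[k], 250.0)
        t += rr
        if t >= total_s * 1000.0:
            break
        t_ms_list.append(t)
        rr_list.append(rr)
        k += 1
    t_ms = np.asarray(t_ms_list)
    rr_ms = np.asarray(rr_list)
    morph = rng.uniform(0.85, 1.0, len(t_ms))
    for s0, s1, kind in corruption:
        sel = (t_ms >= s0 * 1000.0) & (t_ms < s1 * 1000.0)
        if kind == "artifact" and sel.any():
            rr_ms[sel] = rng.uniform(250.0, 3600.0, sel.sum())
            morph[sel] = rng.uniform(0.0, 0.4, sel.sum())

    n_acc = int(total_s * acc_rate_hz)
    acc_t = np.arange(n_acc) / acc_rate_hz * 1000.0
    mag = 1.0 + rng.normal(0.0, 0.012, n_acc)
    for s0, s1, kind in corruption:
        if kind == "activity":
            sel = (acc_t >= s0 * 1000.0) & (acc_t < s1 * 1000.0)
            mag[sel] = 1.0 + rng.normal(0.0, 0.2, sel.sum())
    mag = np.abs(mag)

    stream = BeatStream(pid=pid, t_ms=t_ms, rr_ms=rr_ms, morph_corr=morph,
                        start_time=pd.Timestamp(start_time))
    trace = AccTrace(pid=pid, t_ms=acc_t, mag_g=mag)
    return stream, trace


def _log_mean_exp_correction(sd: float, k: int) -> float:
    """E[log(mean of k iid exp(N(0, sd^2)))], to second order.

    The analysis chain averages heart rate on the bpm scale within each
    condition and only then log-transforms, so minute-level residual
    noise shifts the fitted intercept by this Jensen offset.  The
    generator subtracts it, making the planted intercept the estimand of
    the fitted model.  Zero noise gives zero correction.
    """
    if sd == 0:
        return 0.0
    mean1 = np.exp(sd**2 / 2.0)
    var_k = (np.exp(2 * sd**2) - np.exp(sd**2)) / k
    return float(np.log(mean1) - var_k / (2.0 * mean1**2))


def _mist_predictor(effects: PlantedEffects, dep_high: bool, stress_high: bool) -> np.ndarray:
    """Per-condition planted log-HR means (baseline, training, stress, recovery)."""
    b = effects.mist_betas
    d = 1.0 if dep_high else 0.0
    s = 1.0 if stress_high else 0.0
    base = b["intercept"] + b["dep_high"] * d + b["stress_high"] * s
    out = []
    for cond in MIST_CONDITIONS:
        eta = base
        if cond != "baseline":
            eta += (
                b[f"cond_{cond}"]
                + b[f"cond_{cond}:dep_high"] * d
                + b[f"cond_{cond}:stress_high"] * s
            )
        out.append(eta)
    return np.asarray(out)


def generate_mist_session(
    profile: pd.Series | dict,
    effects: PlantedEffects | None = None,
    seed: int = 0,
    index: int = 0,
) -> pd.DataFrame:
    """Per-minute HR over the 4 x 5-min stress-task schedule for one subject.

    Groups are resolved from the profile's questionnaire totals (DASS-D
    > 6 -> high depressive symptoms; PSS > 18 -> high chronic stress, no
    further subgrouping).  log HR per minute is the planted reactivity
    linear predictor plus the subject's random intercept and residual
    noise.
    """
    effects = effects or PlantedEffects()
    profile = dict(profile)
    rng = participant_rng(seed, index, stage=3)
    dep_high = dep_group(int(profile["dassd"])) == "high"
    stress_high = float(profile["pss"]) > 18.0
    cond_means = _mist_predictor(effects, dep_high, stress_high)
    b0 = rng.normal(0.0, effects.mist_ri_sd) if effects.mist_ri_sd else 0.0
    eps = (
        rng.normal(0.0, effects.mist_resid_sd, 20)
        if effects.mist_resid_sd
        else np.zeros(20)
    )
    minutes = np.arange(20)
    cond = np.repeat(list(MIST_CONDITIONS), 5)
    correction = _log_mean_exp_correction(effects.mist_resid_sd, 5)
    log_hr = cond_means[minutes // 5] - correction + b0 + eps
    return pd.DataFrame(
        {
            "pid": profile.get("pid", f"p{index:05d}"),
            "minute": minutes,
            "condition": cond,
            "mean_hr": np.exp(log_hr),
        }
    )


def generate_mist_cohort(
    profiles: pd.DataFrame, effects: PlantedEffects | None = None, seed: int = 0
) -> pd.DataFrame:
    """Stress-task minutes for every profile (independent substreams)."""
    frames = [
        generate_mist_session(row, effects, seed=seed, index=i)
        for i, (_, row) in enumerate(profiles.iterrows())
    ]
    return pd.concat(frames, ignore_index=True)


def mist_study_profiles(
    n: int = 194, n_dep_high: int = 14, n_stress_high: int = 42, seed: int = 0
) -> pd.DataFrame:
    """Profiles with exact stress-task group sizes.

    Defaults reproduce the stress-task subsample: 194 subjects of whom
    14 score high on depressive symptoms and 42 exceed the PSS cut of 18
    (depression and stress membership drawn independently).
    """
    config = CohortConfig(n_participants=n)
    profiles = generate_profiles(config, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    dep_idx = rng.choice(n, size=n_dep_high, replace=False)
    stress_idx = rng.choice(n, size=n_stress_high, replace=False)
    dassd = np.minimum(rng.poisson(2.0, n), 6)
    dassd[dep_idx] = 7 + np.minimum(rng.poisson(2.0, n_dep_high), 14)
    pss = np.clip(np.round(rng.normal(13.0, 3.5, n)), 0, 18).astype(int)
    pss[stress_idx] = rng.integers(19, 31, n_stress_high)
    out = profiles.copy()
    out["dassd"] = dassd
    out["pss"] = pss
    return out


def aggregate_mist(minutes: pd.DataFrame, qi_threshold: float = 0.8) -> pd.DataFrame:
    """Average QI-passing 1-min windows per stress-task condition.

    Synthetic minutes carry no QI column unless one is added; when
    present, minutes below the threshold are dropped first.
    """
    df = minutes
    if "qi" in df.columns:
        df = df[df["qi"] >= qi_threshold]
    agg = (
        df.groupby(["pid", "condition"], sort=False)
        .agg(mean_hr=("mean_hr", "mean"), n_windows=("mean_hr", "size"))
        .reset_index()
    )
    agg["condition"] = pd.Categorical(
        agg["condition"], categories=list(MIST_CONDITIONS), ordered=True
    )
    return agg.sort_values(["pid", "condition"]).reset_index(drop=True)
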