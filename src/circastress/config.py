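"""Configuration objects for the synthetic cohort and the analysis pipeline.

Two dataclasses carry everything a simulation run needs:

``CohortConfig``
    Demographic and questionnaire distributions of the working cohort
    (sample sizes, age/BMI moments, Perceived-Stress-Scale and DASS
    depression-score distributions, activity categories).

``PlantedEffects``
    The ground-truth coefficients of the generating models on the log
    scale: the circadian harmonic structure of heart rate, covariate and
    group effects, the MIST stress-task fixed effects, and the night-time
    log-RMSSD model.  Defaults equal the published point estimates where
    those are printed; everything else is a documented, tunable choice.

Both are (de)serialisable to a single YAML mapping; unknown keys are
rejected so configuration typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "CohortConfig",
    "PlantedEffects",
    "QualityRules",
    "RecordingSchedule",
    "RunConfig",
    "load_config",
    "dump_config",
]

HARMONIC_PERIODS = (24.0, 12.0, 8.0, 6.0)
#: canonical order of the 8 harmonic basis columns
HARMONIC_NAMES = tuple(
    f"{kind}{int(p)}" for p in HARMONIC_PERIODS for kind in ("sin", "cos")
)

MIST_CONDITIONS = ("baseline", "training", "stress", "recovery")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass
class CohortConfig:
    """Distributional targets for the synthetic working cohort.

    Defaults reproduce the published sample: n = 516 adults, mean age
    39.44 (SD 10.21), 47% women, mean BMI 24.20 (SD 3.78), mean PSS-10
    14.21 (SD 6.01), and a right-skewed DASS depression score with mean
    2.50 (SD 2.91).  The DASS-D is drawn from a negative-binomial
    truncated to 0-21 (dispersion derived from the mean/SD pair); the PSS
    from a normal truncated to 0-40 and rounded to integers.

    ``dep_high_prob`` / ``stress_group_probs`` optionally override the
    score-driven group composition: groups are then assigned first with
    the stated probabilities and questionnaire scores drawn from within
    the matching score band.  This is how small studies with enriched
    extreme-stress arms are emulated.
    """

    n_participants: int = 516
    age_mean: float = 39.44
    age_sd: float = 10.21
    age_bounds: tuple[float, float] = (18.0, 65.0)
    prop_female: float = 0.47
    bmi_mean: float = 24.20
    bmi_sd: float = 3.78
    bmi_bounds: tuple[float, float] = (16.0, 45.0)
    smoking_prob: float = 0.072
    activity_category_probs: tuple[float, ...] = (0.10, 0.25, 0.35, 0.20, 0.10)
    pss_mean: float = 14.21
    pss_sd: float = 6.01
    dassd_mean: float = 2.50
    dassd_sd: float = 2.91
    missing_bmi_prob: float = 0.02
    dep_high_prob: float | None = None
    stress_group_probs: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        for name in ("prop_female", "smoking_prob", "missing_bmi_prob"):
            _check_prob(name, getattr(self, name))
        probs = tuple(float(p) for p in self.activity_category_probs)
        if len(probs) != 5:
            raise ConfigError("activity_category_probs needs exactly 5 entries")
        for p in probs:
            _check_prob("activity_category_probs", p)
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("activity_category_probs must sum to 1")
        self.activity_category_probs = probs
        if self.dep_high_prob is not None:
            _check_prob("dep_high_prob", self.dep_high_prob)
        if self.stress_group_probs is not None:
            sp = tuple(float(p) for p in self.stress_group_probs)
            if len(sp) != 3:
                raise ConfigError("stress_group_probs needs 3 entries")
            for p in sp:
                _check_prob("stress_group_probs", p)
            if abs(sum(sp) - 1.0) > 1e-9:
                raise ConfigError("stress_group_probs must sum to 1")
            self.stress_group_probs = sp
        if any(sd < 0 for sd in (self.age_sd, self.bmi_sd, self.pss_sd, self.dassd_sd)):
            raise ConfigError("scale parameters must be non-negative")

    @property
    def dassd_dispersion(self) -> float:
        """Negative-binomial size parameter implied by the mean/SD pair."""
        var = self.dassd_sd**2
        if var <= self.dassd_mean:
            raise ConfigError("DASS-D variance must exceed its mean (overdispersion)")
        return self.dassd_mean**2 / (var - self.dassd_mean)


def _default_harmonics() -> dict[str, float]:
    # 24-h component phased for an early-afternoon peak and a ~2:30 a.m.
    # trough; 12-h sine and 8-h cosine mains negative so that positive
    # extreme-stress interactions blunt the evening peak, mirroring the
    # published simulation curves.
    return {
        "sin24": -0.055,
        "cos24": -0.071,
        "sin12": -0.022,
        "cos12": 0.008,
        "sin8": 0.006,
        "cos8": -0.011,
        "sin6": 0.003,
        "cos6": -0.002,
    }


def _default_covariates() -> dict[str, float]:
    # log-HR effects of min-max rescaled covariates; plausible magnitudes,
    # not published quantities.
    return {
        "age": -0.04,
        "bmi": 0.08,
        "sex_female": 0.04,
        "smoking": 0.04,
        "activity": 0.15,
    }


def _default_mist_betas() -> dict[str, float]:
    # fixed effects of the MIST reactivity model (log-HR scale), in
    # reference coding: depression low / chronic stress normative /
    # baseline condition.
    return {
        "intercept": 4.239,
        "dep_high": 0.076,
        "stress_high": -0.018,
        "cond_training": 0.006,
        "cond_stress": 0.028,
        "cond_recovery": 0.0003,
        "cond_training:dep_high": -0.003,
        "cond_stress:dep_high": -0.037,
        "cond_recovery:dep_high": -0.020,
        "cond_training:stress_high": 0.013,
        "cond_stress:stress_high": 0.025,
        "cond_recovery:stress_high": 0.007,
    }


def _default_rmssd_betas() -> dict[str, float]:
    # night-time log-RMSSD model: intercept block, group effects and the
    # within-night linear time trend (time = 1..8 for 22:00..05:00).
    return {
        "intercept": 3.90,
        "age": -0.50,
        "bmi": -0.15,
        "sex_female": 0.05,
        "smoking": -0.05,
        "activity": -0.10,
        "dep_high": 0.088,
        "stress_high": 0.041,
        "stress_extreme": 0.177,
        "dep_high:stress_high": -0.099,
        "dep_high:stress_extreme": -0.210,
        "time": 0.015,
        "time:dep_high": -0.005,
        "time:stress_high": -0.003,
        "time:stress_extreme": -0.008,
        "time:dep_high:stress_high": -0.004,
        "time:dep_high:stress_extreme": -0.010,
    }


@dataclass
class PlantedEffects:
    """Ground-truth generating coefficients (log scale).

    Circadian heart rate::

        log HR(t) = beta0 + harmonics(t) + covariates + group terms
                    + b0_i + b_i' harmonics(t) + eps

    ``stress_main`` holds the chronic-stress shifts in the low-depression
    stratum (high +0.031; extreme 0), ``dep_stress_main`` the additional
    shifts in the high-depression stratum so that its totals are high 0 /
    extreme -0.084, and ``dep_stress_circadian`` the extreme-stress
    harmonic interactions active only with high depressive symptoms
    (sin 12 h +0.022, cos 8 h +0.011).

    ``mist_betas`` are the 12 fixed effects of the stress-task model and
    ``rmssd_night_betas`` the night-time log-RMSSD model.  Random-effect
    and residual SDs are not published; defaults are calibrated so the
    simulated between/within variance split gives a conditional R^2 near
    0.75 on the log-HR model.
    """

    beta0: float = 4.2157
    target_mean_hr: float | None = 67.87
    harmonic_betas: dict[str, float] = field(default_factory=_default_harmonics)
    covariate_betas: dict[str, float] = field(default_factory=_default_covariates)
    dep_main: float = 0.0
    stress_main: dict[str, float] = field(
        default_factory=lambda: {"high": 0.031, "extreme": 0.0}
    )
    dep_stress_main: dict[str, float] = field(
        default_factory=lambda: {"high": -0.031, "extreme": -0.084}
    )
    dep_stress_circadian: dict[str, float] = field(
        default_factory=lambda: {"extreme:sin12": 0.022, "extreme:cos8": 0.011}
    )
    ri_sd: float = 0.10
    rslope_sds: dict[str, float] = field(
        default_factory=lambda: {name: 0.02 for name in HARMONIC_NAMES}
    )
    resid_sd: float = 0.05
    mist_betas: dict[str, float] = field(default_factory=_default_mist_betas)
    mist_ri_sd: float = 0.13
    mist_resid_sd: float = 0.10
    rmssd_night_betas: dict[str, float] = field(default_factory=_default_rmssd_betas)
    rmssd_ri_sd: float = 0.30
    rmssd_time_sd: float = 0.02
    rmssd_resid_sd: float = 0.20

    def __post_init__(self) -> None:
        for name in (
            "ri_sd",
            "resid_sd",
            "mist_ri_sd",
            "mist_resid_sd",
            "rmssd_ri_sd",
            "rmssd_time_sd",
            "rmssd_resid_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for k, v in self.rslope_sds.items():
            if k not in HARMONIC_NAMES:
                raise ConfigError(f"unknown harmonic slope {k!r}")
            if v < 0:
                raise ConfigError("random-slope SDs must be >= 0")
        missing = set(HARMONIC_NAMES) - set(self.harmonic_betas)
        if missing:
            raise ConfigError(f"harmonic_betas missing terms: {sorted(missing)}")

    def with_zero_noise(self) -> "PlantedEffects":
        """Copy with every random-effect and residual SD forced to zero."""
        out = dataclasses.replace(
            self,
            ri_sd=0.0,
            resid_sd=0.0,
            mist_ri_sd=0.0,
            mist_resid_sd=0.0,
            rmssd_ri_sd=0.0,
            rmssd_time_sd=0.0,
            rmssd_resid_sd=0.0,
        )
        out.rslope_sds = {k: 0.0 for k in self.rslope_sds}
        return out


@dataclass
class RecordingSchedule:
    """Ambulatory recording span and hourly missingness.

    The default span runs Thursday 09:00 to Monday 17:00 (104 h); hourly
    records are then dropped independently so the expected yield matches
    the published ~84 valid hourly averages per participant.
    """

    start: str = "2019-09-05 09:00"  # a Thursday
    duration_hours: int = 104
    hour_missing_prob: float = 0.194

    def __post_init__(self) -> None:
        if self.duration_hours < 24:
            raise ConfigError("recording span must cover at least 24 h")
        _check_prob("hour_missing_prob", self.hour_missing_prob)


@dataclass
class QualityRules:
    """Rule-based ECG signal-quality criteria applied per 10-s sub-segment.

    A sub-segment passes when the implied heart rate stays physiological,
    no inter-beat gap exceeds ``max_rr_gap_s``, the max/min RR ratio is
    bounded and the mean beat-morphology correlation is high enough.  The
    window QI is the passing fraction of its sub-segments.
    """

    hr_min: float = 40.0
    hr_max: float = 180.0
    max_rr_gap_s: float = 3.0
    max_rr_ratio: float = 2.2
    min_morph_corr: float = 0.66
    subsegment_s: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.hr_min < self.hr_max:
            raise ConfigError("need 0 < hr_min < hr_max")
        if min(self.max_rr_gap_s, self.max_rr_ratio, self.subsegment_s) <= 0:
            raise ConfigError("quality bounds must be positive")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> preprocess -> fit)."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    effects: PlantedEffects = field(default_factory=PlantedEffects)
    schedule: RecordingSchedule = field(default_factory=RecordingSchedule)
    quality: QualityRules = field(default_factory=QualityRules)
    qi_threshold: float = 0.8
    std_acc_threshold: float = 0.04
    min_windows_per_hour: int = 5
    pss_mode: str = "percentile"  # or "fixed"
    stepwise: bool = True
    contrast_weights: str = "proportional"  # or "equal"
    stages: tuple[str, ...] = ("simulate", "group", "fit")

    def __post_init__(self) -> None:
        _check_prob("qi_threshold", self.qi_threshold)
        if self.std_acc_threshold < 0:
            raise ConfigError("std_acc_threshold must be >= 0")
        if self.min_windows_per_hour < 1:
            raise ConfigError("min_windows_per_hour must be >= 1")
        if self.pss_mode not in ("percentile", "fixed"):
            raise ConfigError("pss_mode must be 'percentile' or 'fixed'")
        if self.contrast_weights not in ("proportional", "equal"):
            raise ConfigError("contrast_weights must be 'proportional' or 'equal'")


_SECTIONS = {
    "cohort": CohortConfig,
    "effects": PlantedEffects,
    "schedule": RecordingSchedule,
    "quality": QualityRules,
}


def _build(cls: type, mapping: dict[str, Any]) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path_or_mapping: Any) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML file path or a mapping."""
    if isinstance(path_or_mapping, dict):
        raw = dict(path_or_mapping)
    else:
        with open(path_or_mapping, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    kwargs: dict[str, Any] = {}
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    for key, value in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], value or {})
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: Any = None) -> str:
    """Serialise a :class:`RunConfig` to YAML (returned; optionally written)."""
    text = yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
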