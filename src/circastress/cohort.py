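"""Synthetic participant profiles for the working-cohort generator.

Each participant gets demographics (age, sex, BMI, smoking, weekly sport
category), a PSS-10 total and a DASS depression total.  Ages and BMI are
truncated normals; the PSS is a truncated normal rounded to integers;
the DASS-D is a negative binomial truncated to 0-21, whose dispersion is
derived from the configured mean/SD so the distribution is right-skewed
the way depression scores are in a non-clinical working population.

Every participant draws from an independent, deterministic substream
(``SeedSequence([seed, index])``), so enlarging the cohort never
reshuffles existing participants.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .config import CohortConfig
from .groups import FIXED_PSS_CUTS

__all__ = ["generate_profiles", "participant_rng"]


def participant_rng(seed: int, index: int, stage: int = 0) -> np.random.Generator:
    """Deterministic per-participant, per-stage random substream."""
    return np.random.default_rng(np.random.SeedSequence([seed, index, stage]))


@lru_cache(maxsize=128)
def _calibrated_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """(loc, scale) whose [lo, hi]-truncated normal has the target moments.

    Plain truncation biases the mean toward the centre of the bounds and
    shrinks the SD; solving for the underlying parameters keeps the
    configured sample moments recoverable.
    """
    from scipy import optimize

    def eqs(p):
        loc, scale = p[0], abs(p[1])
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, _ = optimize.fsolve(eqs, [mean, sd], full_output=True)
    if ier != 1:
        return mean, sd
    return float(sol[0]), float(abs(sol[1]))


def _trunc_normal(u: float, mean: float, sd: float, lo: float, hi: float,
                  band: tuple[float, float] | None = None) -> float:
    """Moment-calibrated truncated-normal quantile; optional sub-band."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    loc, scale = _calibrated_truncnorm(mean, sd, lo, hi)
    blo, bhi = band if band is not None else (lo, hi)
    a, b = (max(lo, blo) - loc) / scale, (min(hi, bhi) - loc) / scale
    return float(stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale))


def _draw_dassd(rng: np.random.Generator, config: CohortConfig, high: bool | None) -> int:
    """Truncated negative-binomial DASS-D, optionally conditioned on group."""
    r = config.dassd_dispersion
    p = r / (r + config.dassd_mean)
    for _ in range(1000):
        val = int(min(rng.negative_binomial(r, p), 21))
        if high is None or (val > 6) == high:
            return val
    # conditioning on the rare tail can exhaust rejection sampling
    return 7 + int(min(rng.poisson(2.0), 14)) if high else int(rng.integers(0, 7))


def _draw_pss(rng: np.random.Generator, config: CohortConfig, level: str | None) -> int:
    cut1, cut2 = FIXED_PSS_CUTS
    if level is None:
        return int(round(_trunc_normal(rng.uniform(), config.pss_mean, config.pss_sd, 0, 40)))
    if level == "normative":
        return int(round(_trunc_normal(rng.uniform(), config.pss_mean, config.pss_sd,
                                       0, 40, band=(0, cut1))))
    if level == "high":
        return int(rng.integers(int(cut1) + 1, int(cut2) + 1))  # 19..24
    return int(rng.integers(int(cut2) + 1, 34))  # 25..33


def generate_profiles(config: CohortConfig, seed: int = 0) -> pd.DataFrame:
    """Draw a cohort of participant profiles.

    Returns a DataFrame with columns pid, age, sex, bmi (NaN where
    missing), smoking, activity_hours_cat, pss, dassd.  When the config
    overrides group shares (``dep_high_prob`` / ``stress_group_probs``),
    groups are assigned first and questionnaire totals drawn from within
    the matching score band so re-derived labels equal the planted ones.
    """
    rows = []
    act_probs = np.asarray(config.activity_category_probs)
    stress_levels = ("normative", "high", "extreme")
    for i in range(config.n_participants):
        rng = participant_rng(seed, i, stage=0)
        dep_high = None
        if config.dep_high_prob is not None:
            dep_high = bool(rng.uniform() < config.dep_high_prob)
        stress_level = None
        if config.stress_group_probs is not None:
            stress_level = stress_levels[
                int(rng.choice(3, p=np.asarray(config.stress_group_probs)))
            ]
        bmi = _trunc_normal(rng.uniform(), config.bmi_mean, config.bmi_sd, *config.bmi_bounds)
        if rng.uniform() < config.missing_bmi_prob:
            bmi = float("nan")
        rows.append(
            {
                "pid": f"p{i:05d}",
                "age": _trunc_normal(
                    rng.uniform(), config.age_mean, config.age_sd, *config.age_bounds
                ),
                "sex": "female" if rng.uniform() < config.prop_female else "male",
                "bmi": bmi,
                "smoking": bool(rng.uniform() < config.smoking_prob),
                "activity_hours_cat": int(rng.choice(5, p=act_probs)),
                "pss": _draw_pss(rng, config, stress_level),
                "dassd": _draw_dassd(rng, config, dep_high),
            }
        )
    columns = ["pid", "age", "sex", "bmi", "smoking", "activity_hours_cat", "pss", "dassd"]
    return pd.DataFrame(rows, columns=columns)
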