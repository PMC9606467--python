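"""Model classes for the circadian, night-RMSSD and stress-reactivity analyses.

Organised statsmodels-style: a model object is built from data tables
(hourly physiology, cohort covariates, group labels), its ``fit()``
returns a results object carrying estimates, standard errors, AIC and a
``summary()`` table, and simulation/contrast utilities hang off the
results.

The three analyses:

``CircadianHRModel``
    log hourly HR on 8 harmonic terms (periods 24/12/8/6 h of the
    wall-clock hour of day), rescaled covariates (age, BMI, sex,
    smoking, hourly activity index) and depression / chronic-stress
    group factors with harmonic interactions; per-subject random
    intercept plus independent random slopes for every harmonic term.
    The overall model is backward-AIC-selected; split-by-depression
    models are fitted directly.

``NightRMSSDModel``
    log hourly RMSSD between 22:00 and 05:00 on a linear night-time
    index (1..8), covariates and the full depression x stress factorial
    with time interactions; random intercept + random time slope; full
    model, no selection.

``ReactivityModel``
    log per-condition HR over the 4-condition stress task (baseline,
    training, stress, recovery) on depression group, binary chronic
    stress and condition with both group x condition interactions;
    random intercept per subject.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import HARMONIC_NAMES, MIST_CONDITIONS
from .contrasts import pairwise_contrasts
from .design import Term, build_design, interaction
from .groups import assign_groups, minmax_rescale
from .harmonics import harmonic_design
from .lmm import LmmFit, fit_lmm, wald_joint_test
from .selection import backward_stepwise
from .windows import coverage_filter, night_subset

__all__ = [
    "CircadianHRModel",
    "NightRMSSDModel",
    "ReactivityModel",
    "MixedModelResults",
    "CircadianResults",
    "ReactivityResults",
    "fit_circadian_overall",
    "fit_circadian_split",
    "fit_night_rmssd",
    "fit_reactivity",
    "type3_tests",
]


def _rescale_quiet(values):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return minmax_rescale(values)


def _covariate_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    bmi = cohort["bmi"].to_numpy(dtype=float)
    if np.isnan(bmi).any() and not np.isnan(bmi).all():
        bmi = np.where(np.isnan(bmi), np.nanmedian(bmi), bmi)
    return pd.DataFrame(
        {
            "pid": cohort["pid"],
            "age_r": _rescale_quiet(cohort["age"].to_numpy(dtype=float)),
            "bmi_r": _rescale_quiet(np.nan_to_num(bmi)),
            "sex_female": (cohort["sex"] == "female").astype(float),
            "smoking": cohort["smoking"].astype(float),
        }
    )


def _resolve_groups(cohort, groups, pss_mode: str) -> pd.DataFrame:
    if groups is None:
        return assign_groups(cohort, mode=pss_mode).table
    if hasattr(groups, "table"):
        return groups.table
    return groups


def _factor_terms():
    dep = Term.make("dep", {"dep[high]": ["dep_high"]})
    stress = Term.make(
        "stress",
        {"stress[high]": ["stress_high"], "stress[extreme]": ["stress_extreme"]},
    )
    return dep, stress


def _covariate_terms(frame: pd.DataFrame | None = None):
    terms = [
        Term.make("age", {"age": ["age_r"]}),
        Term.make("bmi", {"bmi": ["bmi_r"]}),
        Term.make("sex", {"sex[female]": ["sex_female"]}),
        Term.make("smoking", {"smoking": ["smoking"]}),
        Term.make("activity", {"activity": ["activity_r"]}),
    ]
    if frame is None:
        return terms
    kept = []
    for t in terms:
        col = t.columns[0][1][0]
        if np.ptp(frame[col].to_numpy(dtype=float)) == 0.0:
            # constant within the analysis subset: uninformative and
            # aliased with the intercept (e.g. no smokers in a stratum)
            warnings.warn(f"dropping constant covariate {t.name!r}", stacklevel=3)
            continue
        kept.append(t)
    return kept


class MixedModelResults:
    """Shared results wrapper: delegation to the fit plus term-aware tests."""

    def __init__(self, model, fit: LmmFit, terms: list[Term],
                 trace: pd.DataFrame | None = None):
        self.model = model
        self.fit = fit
        self.terms = terms
        self.stepwise_trace = trace

    # statsmodels-flavoured delegation
    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def bse(self) -> pd.Series:
        return self.fit.bse

    @property
    def tvalues(self) -> pd.Series:
        return self.fit.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self.fit.pvalues

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def llf(self) -> float:
        return self.fit.loglik

    @property
    def r2_conditional(self) -> float:
        return self.fit.r2_conditional

    def coefficients(self) -> pd.DataFrame:
        return self.fit.coefficients

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise ValueError(f"term {name!r} not in the fitted model")

    def type3_test(self, factor: str):
        """Joint Wald F-test over all coefficients of one term/factor."""
        return wald_joint_test(self.fit, self.term(factor).column_names)

    def summary(self) -> str:
        out = [self.fit.summary()]
        if self.stepwise_trace is not None and len(self.stepwise_trace):
            dropped = self.stepwise_trace.query("action == 'dropped'")["term"].tolist()
            out.append(f"Stepwise-dropped terms: {dropped or 'none'}")
        return "\n".join(out)


class CircadianResults(MixedModelResults):
    def simulate_curves(self, grid: np.ndarray | None = None) -> pd.DataFrame:
        """Group-level predicted log-HR curves over the 24-h day.

        The linear predictor is evaluated on a dense hour grid using only
        the intercept, harmonic and group-related terms: covariates (BMI,
        sex, age, smoking, activity) are zeroed, so curves isolate the
        circadian and group structure.
        """
        if grid is None:
            grid = np.arange(0.0, 24.0, 0.25)
        dep_levels = ["low", "high"] if self.model.stratum is None else [self.model.stratum]
        rows = []
        for dep_level in dep_levels:
            for stress_level in ("normative", "high", "extreme"):
                frame = harmonic_design(grid)
                frame["intercept"] = 1.0
                for c in ("age_r", "bmi_r", "sex_female", "smoking", "activity_r"):
                    frame[c] = 0.0
                frame["dep_high"] = 1.0 if dep_level == "high" else 0.0
                frame["stress_high"] = 1.0 if stress_level == "high" else 0.0
                frame["stress_extreme"] = 1.0 if stress_level == "extreme" else 0.0
                X, names = build_design(frame, self.terms)
                pred = X @ self.params.reindex(names).to_numpy()
                rows.append(
                    pd.DataFrame(
                        {
                            "dep_group": dep_level,
                            "stress_group": stress_level,
                            "hour": grid,
                            "log_hr": pred,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


class ReactivityResults(MixedModelResults):
    def pairwise_contrasts(self, stratify_by: str = "dep_group",
                           weights: str | None = None) -> pd.DataFrame:
        """All 6 condition contrasts per stratum, BH-adjusted within stratum."""
        weights = weights or self.model.contrast_weights
        return pairwise_contrasts(
            self.fit,
            stratify_by=stratify_by,
            stress_share=self.model.stress_share,
            dep_share=self.model.dep_share,
            weights=weights,
        )


class CircadianHRModel:
    """Harmonic mixed model for log hourly heart rate.

    Parameters
    ----------
    hourly : DataFrame with pid, hour_of_day, mean_hr, activity_index.
    cohort : participant table (pid, age, sex, bmi, smoking, ...).
    groups : optional GroupAssignment or table (pid, dep_group,
        stress_group); derived from the questionnaire totals at the
        published cuts when omitted.
    stratum : None for the overall model (depression terms + three-way
        interactions included), or 'low'/'high' to fit within one
        depressive-symptom stratum (no depression terms).
    apply_coverage : drop participants lacking any of the 24 clock hours.
    """

    def __init__(self, hourly, cohort, groups=None, stratum=None,
                 pss_mode: str = "fixed", apply_coverage: bool = True):
        if stratum not in (None, "low", "high"):
            raise ValueError("stratum must be None, 'low' or 'high'")
        self.stratum = stratum
        gtab = _resolve_groups(cohort, groups, pss_mode)
        data = hourly.copy()
        if apply_coverage:
            data = coverage_filter(data)
        data = data.merge(gtab, on="pid").merge(_covariate_frame(cohort), on="pid")
        if stratum is not None:
            data = data[data["dep_group"] == stratum].reset_index(drop=True)
        if data.empty:
            raise ValueError("no observations after filtering")
        basis = harmonic_design(data["hour_of_day"].to_numpy())
        for c in basis.columns:
            data[c] = basis[c].to_numpy()
        data["intercept"] = 1.0
        data["activity_r"] = _rescale_quiet(data["activity_index"].to_numpy(dtype=float))
        data["dep_high"] = (data["dep_group"] == "high").astype(float)
        data["stress_high"] = (data["stress_group"] == "high").astype(float)
        data["stress_extreme"] = (data["stress_group"] == "extreme").astype(float)
        data["log_hr"] = np.log(data["mean_hr"].to_numpy(dtype=float))
        self.frame = data
        self.terms = self._build_terms()
        self.random_names = ["ri"] + list(HARMONIC_NAMES)

    def _build_terms(self) -> list[Term]:
        intercept = Term.make("intercept", {"intercept": []}, protected=True)
        dep, stress = _factor_terms()
        terms = [intercept] + _covariate_terms(self.frame)
        include_dep = self.stratum is None
        if include_dep:
            terms.append(dep)
        terms.append(stress)
        for period in (24, 12, 8, 6):
            h = Term.make(
                f"h{period}",
                {f"sin{period}": [f"sin{period}"], f"cos{period}": [f"cos{period}"]},
            )
            terms.append(h)
            terms.append(interaction(stress, h, name=f"stress:h{period}"))
            if include_dep:
                terms.append(interaction(dep, h, name=f"dep:h{period}"))
                three = interaction(dep, interaction(stress, h), name=f"dep:stress:h{period}",
                                    parents=(f"dep:h{period}", f"stress:h{period}"))
                terms.append(three)
        return terms

    def _z(self) -> np.ndarray:
        cols = [np.ones(len(self.frame))]
        cols += [self.frame[c].to_numpy() for c in HARMONIC_NAMES]
        return np.column_stack(cols)

    def _fit_terms(self, terms: list[Term], method: str) -> LmmFit:
        X, names = build_design(self.frame, terms)
        return fit_lmm(
            y=self.frame["log_hr"].to_numpy(),
            X=X,
            x_names=names,
            groups=self.frame["pid"].to_numpy(),
            Z=self._z(),
            z_names=self.random_names,
            method=method,
        )

    def fit(self, method: str = "reml", stepwise: bool | None = None,
            protected: tuple[str, ...] = ()) -> CircadianResults:
        """Fit the model; overall models are stepwise-selected by default."""
        if stepwise is None:
            stepwise = self.stratum is None
        if stepwise:
            final, kept, trace = backward_stepwise(self.terms, self._fit_terms,
                                                   protected=protected)
            return CircadianResults(self, final, kept, trace)
        return CircadianResults(self, self._fit_terms(self.terms, method), self.terms)


class NightRMSSDModel:
    """Linear-time mixed model for log night-time RMSSD (22:00-05:00).

    Accepts the full hourly table (the night subset and the time index
    1..8 are derived internally) or a pre-subset table already carrying
    a ``time`` column.  The full depression x chronic-stress factorial
    interacts with the intercept and the time slope; no model selection
    is performed.
    """

    def __init__(self, hourly, cohort, groups=None, pss_mode: str = "fixed"):
        gtab = _resolve_groups(cohort, groups, pss_mode)
        data = hourly if "time" in hourly.columns else night_subset(hourly)
        data = data.merge(gtab, on="pid").merge(_covariate_frame(cohort), on="pid")
        if data.empty:
            raise ValueError("no night-time observations")
        data = data.copy()
        data["intercept"] = 1.0
        data["activity_r"] = _rescale_quiet(data["activity_index"].to_numpy(dtype=float))
        data["dep_high"] = (data["dep_group"] == "high").astype(float)
        data["stress_high"] = (data["stress_group"] == "high").astype(float)
        data["stress_extreme"] = (data["stress_group"] == "extreme").astype(float)
        data["time"] = data["time"].astype(float)
        data["log_rmssd"] = np.log(data["mean_rmssd"].to_numpy(dtype=float))
        self.frame = data
        dep, stress = _factor_terms()
        time = Term.make("time", {"time": ["time"]})
        self.terms = (
            [Term.make("intercept", {"intercept": []}, protected=True)]
            + _covariate_terms(self.frame)
            + [
                dep,
                stress,
                interaction(dep, stress),
                time,
                interaction(time, dep, name="time:dep"),
                interaction(time, stress, name="time:stress"),
                interaction(time, interaction(dep, stress), name="time:dep:stress",
                            parents=("time:dep", "time:stress")),
            ]
        )

    def fit(self, method: str = "reml") -> MixedModelResults:
        X, names = build_design(self.frame, self.terms)
        fit = fit_lmm(
            y=self.frame["log_rmssd"].to_numpy(),
            X=X,
            x_names=names,
            groups=self.frame["pid"].to_numpy(),
            Z=np.column_stack([np.ones(len(self.frame)), self.frame["time"].to_numpy()]),
            z_names=["ri", "time"],
            method=method,
        )
        return MixedModelResults(self, fit, self.terms)


class ReactivityModel:
    """Stress-task (MIST) reactivity model for log per-condition HR.

    ``records`` holds one row per subject x condition with ``mean_hr``
    averaged over the QI-passing 1-min windows.  Chronic stress enters
    as a binary factor (normative vs high, merging high and extreme).
    Stratum-level pairwise contrasts average over the other grouping
    factor; by default with the observed group proportions as weights.
    """

    def __init__(self, records, cohort=None, groups=None, pss_mode: str = "fixed",
                 contrast_weights: str = "proportional"):
        if groups is None and cohort is not None:
            groups = assign_groups(cohort, mode=pss_mode).table
        if groups is None:
            raise ValueError("need either a groups table or a cohort table")
        gtab = groups.table if hasattr(groups, "table") else groups
        data = records.merge(gtab, on="pid")
        data = data.copy()
        data["condition"] = data["condition"].astype(str)
        present = set(data["condition"])
        missing = set(MIST_CONDITIONS) - present
        if missing:
            raise ValueError(f"conditions absent from the data: {sorted(missing)}")
        counts = data.groupby("pid")["condition"].nunique()
        lacking = counts[counts < 2].index
        if len(lacking):
            warnings.warn(
                f"dropping {len(lacking)} subjects with < 2 conditions", stacklevel=2
            )
            data = data[~data["pid"].isin(lacking)]
        data["intercept"] = 1.0
        data["dep_high"] = (data["dep_group"] == "high").astype(float)
        data["stress_high"] = (data["stress_group"] != "normative").astype(float)
        for cond in MIST_CONDITIONS[1:]:
            data[f"c_{cond}"] = (data["condition"] == cond).astype(float)
        data["log_hr"] = np.log(data["mean_hr"].to_numpy(dtype=float))
        self.frame = data.reset_index(drop=True)
        self.contrast_weights = contrast_weights
        per_subject = self.frame.drop_duplicates("pid")
        self.stress_share = float(per_subject["stress_high"].mean())
        self.dep_share = float(per_subject["dep_high"].mean())
        dep = Term.make("dep", {"dep[high]": ["dep_high"]})
        stress = Term.make("stress", {"stress[high]": ["stress_high"]})
        cond = Term.make(
            "cond", {f"cond[{c}]": [f"c_{c}"] for c in MIST_CONDITIONS[1:]}
        )
        self.terms = [
            Term.make("intercept", {"intercept": []}, protected=True),
            dep,
            stress,
            cond,
            interaction(cond, dep, name="cond:dep"),
            interaction(cond, stress, name="cond:stress"),
        ]

    def fit(self, method: str = "reml") -> ReactivityResults:
        X, names = build_design(self.frame, self.terms)
        fit = fit_lmm(
            y=self.frame["log_hr"].to_numpy(),
            X=X,
            x_names=names,
            groups=self.frame["pid"].to_numpy(),
            Z=np.ones((len(self.frame), 1)),
            z_names=["ri"],
            method=method,
        )
        return ReactivityResults(self, fit, self.terms)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_circadian_overall(hourly, cohort, groups=None, stepwise: bool = True,
                          **kwargs) -> CircadianResults:
    """Overall circadian log-HR model with backward AIC selection."""
    return CircadianHRModel(hourly, cohort, groups, stratum=None, **kwargs).fit(
        stepwise=stepwise
    )


def fit_circadian_split(hourly, cohort, groups=None, stratum: str = "low",
                        stepwise: bool = False, **kwargs) -> CircadianResults:
    """Circadian model within one depressive-symptom stratum."""
    return CircadianHRModel(hourly, cohort, groups, stratum=stratum, **kwargs).fit(
        stepwise=stepwise
    )


def fit_night_rmssd(hourly, cohort, groups=None, **kwargs) -> MixedModelResults:
    """Full (unselected) night-time log-RMSSD model."""
    return NightRMSSDModel(hourly, cohort, groups, **kwargs).fit()


def fit_reactivity(records, cohort=None, groups=None, **kwargs) -> ReactivityResults:
    """Stress-task reactivity model (random intercept per subject)."""
    return ReactivityModel(records, cohort, groups, **kwargs).fit()


def type3_tests(results: MixedModelResults, factor: str):
    """Joint Wald F-test for a factor/interaction of a fitted model."""
    return results.type3_test(factor)
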