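"""Model classes: exact recovery in the noiseless limit, curve
simulation, reactivity contrasts and reparameterisation identities."""

import numpy as np
import pandas as pd
import pytest

from circastress.config import MIST_CONDITIONS, PlantedEffects
from circastress.contrasts import pairwise_contrasts
from circastress.models import (
    CircadianHRModel,
    NightRMSSDModel,
    ReactivityModel,
    fit_circadian_split,
    fit_night_rmssd,
    fit_reactivity,
)
from circastress.simulate import (
    aggregate_mist,
    generate_mist_cohort,
    mist_study_profiles,
    planted_curve,
)
from circastress.windows import night_subset


class TestCircadianNoiselessRecovery:
    def test_split_models_recover_planted_coefficients_exactly(self, boosted_cohort,
                                                               noiseless_hourly):
        hourly, effects = noiseless_hourly
        low = fit_circadian_split(hourly, boosted_cohort, stratum="low")
        assert low.params["stress[high]"] == pytest.approx(0.031, abs=1e-6)
        assert low.params["stress[extreme]"] == pytest.approx(0.0, abs=1e-6)
        for name, value in effects.harmonic_betas.items():
            assert low.params[name] == pytest.approx(value, abs=1e-6)
        high = fit_circadian_split(hourly, boosted_cohort, stratum="high")
        assert high.params["stress[extreme]"] == pytest.approx(-0.084, abs=1e-6)
        assert high.params["stress[extreme]:sin12"] == pytest.approx(0.022, abs=1e-6)
        assert high.params["stress[extreme]:cos8"] == pytest.approx(0.011, abs=1e-6)
        assert high.params["stress[high]"] == pytest.approx(-0.031 + 0.031, abs=1e-6)

    def test_noiseless_conditional_r2_is_one(self, boosted_cohort, noiseless_hourly):
        hourly, _ = noiseless_hourly
        res = fit_circadian_split(hourly, boosted_cohort, stratum="low")
        assert res.r2_conditional == pytest.approx(1.0, abs=1e-6)

    def test_simulated_curves_match_generator_curve(self, boosted_cohort,
                                                    noiseless_hourly):
        hourly, effects = noiseless_hourly
        res = fit_circadian_split(hourly, boosted_cohort, stratum="high")
        grid = np.arange(0.0, 24.0, 0.5)
        curves = res.simulate_curves(grid)
        for stress in ("normative", "extreme"):
            got = curves[curves["stress_group"] == stress]["log_hr"].to_numpy()
            want = planted_curve(effects, "high", stress, grid)
            assert np.allclose(got, want, atol=0.01)

    def test_curves_are_24h_periodic(self, boosted_cohort, noiseless_hourly):
        hourly, _ = noiseless_hourly
        res = fit_circadian_split(hourly, boosted_cohort, stratum="low")
        eps = res.simulate_curves(np.array([0.0, 24.0 - 1e-9]))
        by_group = eps.groupby("stress_group")["log_hr"]
        for _, vals in by_group:
            assert vals.iloc[0] == pytest.approx(vals.iloc[1], abs=1e-6)

    def test_flat_curves_without_harmonic_terms(self, boosted_cohort, noiseless_hourly):
        hourly, _ = noiseless_hourly
        model = CircadianHRModel(hourly, boosted_cohort, stratum="low")
        keep = [t for t in model.terms
                if not (t.name.startswith("h") or ":h" in t.name)]
        fit = model._fit_terms(keep, "reml")
        from circastress.models import CircadianResults

        results = CircadianResults(model, fit, keep)
        curves = results.simulate_curves(np.arange(0, 24, 1.0))
        for _, sub in curves.groupby("stress_group"):
            assert sub["log_hr"].std() == pytest.approx(0.0, abs=1e-9)

    def test_missing_stratum_level_is_inestimable(self, boosted_cohort,
                                                  noiseless_hourly):
        hourly, _ = noiseless_hourly
        groups = pd.DataFrame(
            {
                "pid": boosted_cohort["pid"],
                "dep_group": "low",
                "stress_group": "normative",
            }
        )
        with pytest.raises(ValueError, match="stress"):
            fit_circadian_split(hourly, boosted_cohort, groups, stratum="low")


class TestNightRmssd:
    def test_noiseless_exact_recovery(self, boosted_cohort, noiseless_hourly):
        hourly, effects = noiseless_hourly
        res = fit_night_rmssd(hourly, boosted_cohort)
        g = effects.rmssd_night_betas
        assert res.params["time"] == pytest.approx(g["time"], abs=1e-6)
        assert res.params["dep[high]"] == pytest.approx(g["dep_high"], abs=1e-6)
        assert res.params["stress[extreme]"] == pytest.approx(g["stress_extreme"], abs=1e-6)
        assert res.params["dep[high]:stress[extreme]"] == pytest.approx(
            g["dep_high:stress_extreme"], abs=1e-6
        )
        assert res.params["time:dep[high]:stress[extreme]"] == pytest.approx(
            g["time:dep_high:stress_extreme"], abs=1e-6
        )

    def test_time_recoding_shifts_intercept_by_slope(self, boosted_cohort,
                                                     noiseless_hourly):
        hourly, _ = noiseless_hourly
        night = night_subset(hourly)
        res1 = NightRMSSDModel(night, boosted_cohort).fit()
        shifted = night.copy()
        shifted["time"] = shifted["time"] - 1.0
        res0 = NightRMSSDModel(shifted, boosted_cohort).fit()
        assert res0.params["intercept"] == pytest.approx(
            res1.params["intercept"] + res1.params["time"], abs=1e-6
        )
        assert res0.params["time"] == pytest.approx(res1.params["time"], abs=1e-8)


class TestReactivity:
    def _noiseless_fit(self):
        effects = PlantedEffects(mist_ri_sd=0.0, mist_resid_sd=0.0)
        prof = mist_study_profiles(n=60, n_dep_high=12, n_stress_high=18, seed=21)
        records = aggregate_mist(generate_mist_cohort(prof, effects, seed=21))
        return fit_reactivity(records, cohort=prof), effects

    def test_noiseless_recovery_of_all_twelve_coefficients(self):
        res, effects = self._noiseless_fit()
        b = effects.mist_betas
        expected = {
            "intercept": b["intercept"],
            "dep[high]": b["dep_high"],
            "stress[high]": b["stress_high"],
        }
        for cond in MIST_CONDITIONS[1:]:
            expected[f"cond[{cond}]"] = b[f"cond_{cond}"]
            expected[f"cond[{cond}]:dep[high]"] = b[f"cond_{cond}:dep_high"]
            expected[f"cond[{cond}]:stress[high]"] = b[f"cond_{cond}:stress_high"]
        for name, value in expected.items():
            assert res.params[name] == pytest.approx(value, abs=1e-8), name

    def test_contrast_antisymmetry_and_reference_identity(self):
        res, effects = self._noiseless_fit()
        fit = res.fit
        fwd = pairwise_contrasts(fit, stress_share=0.0, weights="proportional")
        low = fwd[fwd["stratum"] == "low"].set_index("pair")
        # with the stress weight at 0 the stress-baseline contrast is the
        # raw condition coefficient
        assert low.loc["stress-baseline", "estimate"] == pytest.approx(
            float(fit.params["cond[stress]"]), abs=1e-10
        )
        assert low.loc["recovery-stress", "estimate"] == pytest.approx(
            float(fit.params["cond[recovery]"] - fit.params["cond[stress]"]), abs=1e-10
        )

    def test_missing_condition_errors(self):
        prof = mist_study_profiles(n=10, n_dep_high=2, n_stress_high=2, seed=22)
        records = aggregate_mist(generate_mist_cohort(prof, seed=22))
        records = records[records["condition"] != "recovery"]
        with pytest.raises(ValueError, match="recovery"):
            ReactivityModel(records, cohort=prof)

    def test_adjusted_pvalues_bounded(self):
        res, _ = self._noiseless_fit()
        prof = mist_study_profiles(n=50, n_dep_high=10, n_stress_high=15, seed=23)
        records = aggregate_mist(generate_mist_cohort(prof, seed=23))
        noisy = fit_reactivity(records, cohort=prof)
        table = noisy.pairwise_contrasts("dep_group")
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()
        assert (table["p_adj"] <= 1.0).all()

    def test_type3_single_df_matches_t(self):
        res, _ = self._noiseless_fit()
        prof = mist_study_profiles(n=50, n_dep_high=10, n_stress_high=15, seed=24)
        records = aggregate_mist(generate_mist_cohort(prof, seed=24))
        noisy = fit_reactivity(records, cohort=prof)
        F, (df1, _), _ = noisy.type3_test("dep")
        assert df1 == 1
        assert F == pytest.approx(float(noisy.tvalues["dep[high]"] ** 2), rel=1e-9)
        with pytest.raises(ValueError):
            noisy.type3_test("not_a_term")
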