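import numpy as np
import pandas as pd
import pytest

from circastress.cohort import generate_profiles
from circastress.config import CohortConfig, ConfigError, PlantedEffects, RecordingSchedule
from circastress.simulate import (
    aggregate_mist,
    generate_beat_stream,
    generate_hourly_cohort,
    generate_hourly_series,
    generate_mist_session,
    mist_study_profiles,
)
from circastress.windows import compute_window_features, filter_windows

from conftest import zero_effects


class TestProfiles:
    def test_empty_cohort(self):
        assert generate_profiles(CohortConfig(n_participants=0)).empty

    def test_determinism(self):
        a = generate_profiles(CohortConfig(n_participants=40), seed=9)
        b = generate_profiles(CohortConfig(n_participants=40), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_growing_cohort_preserves_existing_participants(self):
        small = generate_profiles(CohortConfig(n_participants=30), seed=9)
        big = generate_profiles(CohortConfig(n_participants=60), seed=9)
        pd.testing.assert_frame_equal(small, big.iloc[:30])

    def test_published_moments_at_large_n(self):
        prof = generate_profiles(CohortConfig(n_participants=5000), seed=2)
        assert prof["pss"].mean() == pytest.approx(14.21, abs=0.3)
        assert prof["pss"].std() == pytest.approx(6.01, abs=0.3)
        assert prof["dassd"].mean() == pytest.approx(2.50, abs=3 * 2.91 / np.sqrt(5000))
        assert prof["age"].mean() == pytest.approx(39.44, abs=3 * 10.21 / np.sqrt(5000))
        assert abs((prof["sex"] == "female").mean() - 0.47) < 3 * 0.5 / np.sqrt(5000)

    def test_dassd_right_skewed(self):
        prof = generate_profiles(CohortConfig(n_participants=500), seed=3)
        x = prof["dassd"].to_numpy(dtype=float)
        c = x - x.mean()
        skew = np.mean(c**3) / np.mean(c**2) ** 1.5
        assert skew > 1.0

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(activity_category_probs=(0.5, 0.5, 0.5, 0.0, 0.0))

    def test_group_share_overrides(self):
        cfg = CohortConfig(n_participants=600, dep_high_prob=0.4,
                           stress_group_probs=(0.2, 0.3, 0.5))
        prof = generate_profiles(cfg, seed=4)
        assert ((prof["dassd"] > 6).mean()) == pytest.approx(0.4, abs=0.07)
        assert ((prof["pss"] > 24).mean()) == pytest.approx(0.5, abs=0.07)


class TestHourlySeries:
    def test_degenerate_model_is_flat_at_intercept(self):
        prof = generate_profiles(CohortConfig(n_participants=1), seed=0)
        eff = zero_effects()
        out = generate_hourly_series(prof.iloc[0], eff,
                                     RecordingSchedule(hour_missing_prob=0.0), seed=0)
        assert np.allclose(np.log(out["mean_hr"]), eff.beta0)

    def test_span_bounds_record_count(self):
        prof = generate_profiles(CohortConfig(n_participants=3), seed=1)
        out = generate_hourly_cohort(prof, seed=1)
        counts = out.groupby("pid").size()
        assert (counts <= 104).all()
        assert out["hour_of_day"].between(0, 23).all()

    def test_missingness_yield_near_published(self):
        prof = generate_profiles(CohortConfig(n_participants=100), seed=2)
        out = generate_hourly_cohort(prof, seed=2)
        assert out.groupby("pid").size().mean() == pytest.approx(83.8, abs=3.0)

    def test_grand_mean_hr_with_planted_intercept_and_noise(self):
        # beta0 = log(67.87), all structure zeroed but noise on; SDs modest
        # enough that the lognormal mean correction stays inside the band
        eff = zero_effects(beta0=np.log(67.87), ri_sd=0.05, resid_sd=0.05)
        prof = generate_profiles(CohortConfig(n_participants=500), seed=0)
        out = generate_hourly_cohort(prof, eff, seed=0)
        grand = out.groupby("pid")["mean_hr"].mean().mean()
        assert grand == pytest.approx(67.87, abs=0.5)

    def test_determinism(self):
        prof = generate_profiles(CohortConfig(n_participants=5), seed=6)
        a = generate_hourly_cohort(prof, seed=6)
        b = generate_hourly_cohort(prof, seed=6)
        pd.testing.assert_frame_equal(a, b)


class TestBeatStream:
    def test_constant_rr_gives_hr60_rmssd0(self):
        stream, acc = generate_beat_stream(duration_h=0.25, target_rmssd=0.0,
                                           mean_hr=60.0, seed=0)
        feats = compute_window_features(stream, acc)
        assert np.allclose(feats["mean_hr"], 60.0)
        assert np.allclose(feats["rmssd"], 0.0)

    def test_clean_stream_passes_all_filters(self):
        stream, acc = generate_beat_stream(duration_h=0.5, target_rmssd=35, seed=1)
        feats = filter_windows(compute_window_features(stream, acc))
        assert feats["retained"].all()

    def test_target_rmssd_calibration(self):
        stream, acc = generate_beat_stream(duration_h=1.0, target_rmssd=52, seed=2)
        feats = compute_window_features(stream, acc)
        assert np.median(feats["rmssd"]) == pytest.approx(52, abs=5)

    def test_overlapping_corruption_rejected(self):
        with pytest.raises(ValueError):
            generate_beat_stream(corruption=[(0, 120, "artifact"), (60, 180, "activity")])

    def test_corruption_monotonically_reduces_retention(self):
        kept = []
        for frac in (0.0, 0.2, 0.4, 0.6):
            segments = [
                (k * 600.0, k * 600.0 + frac * 600.0, "artifact")
                for k in range(6)
                if frac > 0
            ]
            stream, acc = generate_beat_stream(duration_h=1.0, corruption=segments,
                                               target_rmssd=30, seed=3)
            feats = filter_windows(compute_window_features(stream, acc))
            kept.append(int(feats["retained"].sum()))
        assert kept == sorted(kept, reverse=True)

    def test_activity_burst_trips_std_acc_filter(self):
        stream, acc = generate_beat_stream(
            duration_h=0.5, corruption=[(600, 1200, "activity")], target_rmssd=30,
            seed=4,
        )
        feats = filter_windows(compute_window_features(stream, acc))
        burst = feats[(feats["start_s"] >= 600) & (feats["start_s"] < 900)]
        assert (burst["std_acc"] > 0.04).all()
        assert (~burst["retained"]).all()


class TestMistSession:
    def test_schedule_is_twenty_minutes(self):
        prof = mist_study_profiles(n=1, n_dep_high=0, n_stress_high=0, seed=0)
        session = generate_mist_session(prof.iloc[0], seed=0)
        assert len(session) == 20
        assert session["condition"].value_counts().tolist() == [5, 5, 5, 5]

    def test_noiseless_condition_difference_equals_planted(self):
        eff = PlantedEffects(mist_ri_sd=0.0, mist_resid_sd=0.0)
        prof = mist_study_profiles(n=1, n_dep_high=0, n_stress_high=0, seed=1)
        session = generate_mist_session(prof.iloc[0], eff, seed=1)
        means = np.log(session.groupby("condition", sort=False)["mean_hr"].mean())
        assert means["stress"] - means["baseline"] == pytest.approx(
            eff.mist_betas["cond_stress"], abs=1e-12
        )

    def test_reference_group_baseline_level(self):
        prof = mist_study_profiles(n=1000, n_dep_high=0, n_stress_high=0, seed=2)
        minutes = pd.concat(
            [generate_mist_session(row, seed=2, index=i)
             for i, (_, row) in enumerate(prof.iterrows())],
            ignore_index=True,
        )
        base = minutes[minutes["condition"] == "baseline"]
        level = np.exp(np.log(base["mean_hr"]).mean())
        assert level == pytest.approx(np.exp(4.239), abs=1.0)

    def test_aggregate_counts(self):
        prof = mist_study_profiles(n=3, n_dep_high=1, n_stress_high=1, seed=3)
        minutes = pd.concat(
            [generate_mist_session(row, seed=3, index=i)
             for i, (_, row) in enumerate(prof.iterrows())],
            ignore_index=True,
        )
        rec = aggregate_mist(minutes)
        assert len(rec) == 12
        assert (rec["n_windows"] == 5).all()
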