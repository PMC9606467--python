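import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circastress.config import QualityRules
from circastress.simulate import generate_beat_stream
from circastress.windows import (
    BeatStream,
    compute_mean_hr,
    compute_qi,
    compute_rmssd,
    compute_std_acc,
    compute_window_features,
    coverage_filter,
    filter_windows,
    hourly_aggregate,
    night_subset,
    sliding_windows,
)


def constant_stream(duration_s: float, rr_ms: float = 1000.0) -> BeatStream:
    n = int(duration_s * 1000 / rr_ms)
    t = np.arange(1, n + 1) * rr_ms
    return BeatStream("p0", t, np.full(n, rr_ms), np.full(n, 0.95))


class TestSlidingWindows:
    def test_ten_minute_stream_gives_six_windows(self):
        win = sliding_windows(constant_stream(600), length_s=300, step_s=60)
        assert len(win) == 6

    def test_stream_shorter_than_window_gives_none(self):
        assert len(sliding_windows(constant_stream(240), length_s=300, step_s=60)) == 0

    def test_mist_mode_no_overlap(self):
        win = sliding_windows(constant_stream(300), length_s=60, step_s=60)
        assert len(win) == 5


class TestFeatureFormulas:
    def test_rmssd_constant_series_is_zero(self):
        assert compute_rmssd([1000, 1000, 1000]) == 0.0

    def test_rmssd_hand_value(self):
        assert compute_rmssd([800, 810, 790]) == pytest.approx(15.8114, abs=1e-4)

    def test_rmssd_short_series_undefined(self):
        assert np.isnan(compute_rmssd([800, 810]))

    @given(st.lists(st.floats(300, 2000), min_size=3, max_size=50))
    def test_rmssd_reversal_symmetry_and_loop_oracle(self, rr):
        forward = compute_rmssd(rr)
        assert forward == pytest.approx(compute_rmssd(rr[::-1]), abs=1e-9)
        acc = sum((rr[i + 1] - rr[i]) ** 2 for i in range(len(rr) - 1))
        assert forward == pytest.approx(np.sqrt(acc / (len(rr) - 1)), abs=1e-9)

    @pytest.mark.parametrize(
        "rr,expected", [([800] * 5, 75.0), ([1000] * 4, 60.0), ([500, 1500], 80.0)]
    )
    def test_mean_hr_is_beatwise(self, rr, expected):
        assert compute_mean_hr(rr) == pytest.approx(expected)

    def test_std_acc_population_sd(self):
        assert compute_std_acc([0.0, 0.08]) == pytest.approx(0.04)
        assert compute_std_acc([0.5] * 10) == 0.0

    @given(st.lists(st.floats(0, 3), min_size=2, max_size=40), st.floats(0.1, 5))
    def test_std_acc_homogeneous(self, mags, c):
        base = compute_std_acc(mags)
        assert compute_std_acc([c * m for m in mags]) == pytest.approx(
            abs(c) * base, rel=1e-9, abs=1e-12
        )


class TestQualityIndex:
    def test_clean_window_scores_one(self):
        s = constant_stream(300)
        assert compute_qi(s.t_ms, s.rr_ms, s.morph_corr, QualityRules()) == 1.0

    def test_zero_morphology_scores_zero(self):
        s = constant_stream(300)
        qi = compute_qi(s.t_ms, s.rr_ms, np.zeros_like(s.morph_corr), QualityRules())
        assert qi == 0.0

    def test_half_corrupted_scores_half(self):
        s = constant_stream(300)
        morph = s.morph_corr.copy()
        morph[s.t_ms < 150_000] = 0.0  # first 15 of 30 sub-segments fail
        assert compute_qi(s.t_ms, s.rr_ms, morph, QualityRules()) == pytest.approx(0.5)

    def test_empty_window_scores_zero(self):
        assert compute_qi([], [], [], QualityRules()) == 0.0


class TestFilterWindows:
    def _frame(self, qi, std_acc):
        return pd.DataFrame({"qi": [qi], "std_acc": [std_acc]})

    @pytest.mark.parametrize(
        "qi,std_acc,retained,reason",
        [
            (0.79, 0.01, False, "quality"),
            (0.80, 0.04, True, ""),
            (1.00, 0.05, False, "activity"),
            (0.50, 0.10, False, "quality+activity"),
        ],
    )
    def test_boundary_cases(self, qi, std_acc, retained, reason):
        out = filter_windows(self._frame(qi, std_acc))
        assert bool(out["retained"].iloc[0]) is retained
        assert out["exclusion_reason"].iloc[0] == reason

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {"qi": rng.uniform(0, 1, 200), "std_acc": rng.uniform(0, 0.1, 200)}
        )
        kept = [
            filter_windows(frame, qi_threshold=q, std_acc_threshold=s)["retained"].sum()
            for q, s in [(0.6, 0.06), (0.8, 0.06), (0.8, 0.04), (0.9, 0.02)]
        ]
        assert kept == sorted(kept, reverse=True)


class TestHourlyAggregation:
    def _windows(self, hour_hrs):
        rows = []
        for hour, hrs in hour_hrs.items():
            for j, hr in enumerate(hrs):
                rows.append(
                    {
                        "pid": "p0",
                        "clock_hour": pd.Timestamp("2019-09-05") + pd.Timedelta(hours=hour),
                        "hour_of_day": hour % 24,
                        "mean_hr": hr,
                        "rmssd": 40.0,
                        "std_acc": 0.02,
                        "retained": True,
                    }
                )
        return pd.DataFrame(rows)

    def test_mean_and_min_window_rule(self):
        agg = hourly_aggregate(self._windows({9: [60, 61, 62, 63, 64], 10: [70] * 4}))
        assert len(agg) == 1
        assert agg["mean_hr"].iloc[0] == pytest.approx(62.0)

    def test_assignment_by_start_time_splits_counts(self):
        agg = hourly_aggregate(self._windows({9: [60] * 6, 10: [70] * 5}))
        assert agg["n_windows"].tolist() == [6, 5]

    def test_conservation_of_window_counts(self):
        win = self._windows({h: [60 + h] * (5 + h % 3) for h in range(12)})
        agg = hourly_aggregate(win)
        assert agg["n_windows"].sum() == len(win)


class TestCoverageAndNight:
    def _hourly(self, hours, pid="p0"):
        return pd.DataFrame(
            {
                "pid": pid,
                "hour_of_day": hours,
                "mean_hr": 65.0,
                "mean_rmssd": 40.0,
                "activity_index": 0.02,
                "n_windows": 6,
            }
        )

    def test_23_hours_excluded_24_included(self):
        assert len(coverage_filter(self._hourly(list(range(23))))) == 0
        assert len(coverage_filter(self._hourly(list(range(24))))) == 24

    def test_coverage_may_span_days(self):
        # each clock hour appears once but on alternating "days"
        hourly = self._hourly(list(range(0, 24, 2)) + list(range(1, 24, 2)))
        assert len(coverage_filter(hourly)) == 24

    def test_empty_input(self):
        assert coverage_filter(self._hourly([])).empty

    @pytest.mark.parametrize("hour,time", [(22, 1), (23, 2), (0, 3), (3, 6), (5, 8)])
    def test_night_time_index(self, hour, time):
        out = night_subset(self._hourly([hour]))
        assert out["time"].tolist() == [time]

    def test_day_hours_dropped(self):
        assert night_subset(self._hourly([6, 12, 21])).empty


class TestPipelineOnBeats:
    def test_feature_pipeline_idempotent(self):
        stream, acc = generate_beat_stream(duration_h=0.5, target_rmssd=30, seed=5)
        a = compute_window_features(stream, acc)
        b = compute_window_features(stream, acc)
        pd.testing.assert_frame_equal(a, b)
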