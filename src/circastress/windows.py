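"""Windowed feature extraction from beat streams and accelerometer traces.

The ambulatory pre-processing chain: beat annotations (RR interval +
per-beat morphology correlation) and acceleration magnitudes are cut into
5-min windows with 4 min of overlap; each window gets a mean heart rate,
RMSSD, acceleration SD (Std Acc) and a rule-based signal-quality index
(QI).  Windows with QI < 0.8 or Std Acc > 0.04 g are excluded; survivors
are averaged into hourly records (kept only when backed by at least 5
windows).  Participants lacking coverage of any of the 24 clock hours
are excluded from circadian modelling.  Night-time records (22:00-05:00)
get a linear time index 1..8 for the RMSSD model.

Timestamps are milliseconds from recording start; the recording start is
anchored to a wall-clock datetime for hour-of-day computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QualityRules

__all__ = [
    "BeatStream",
    "AccTrace",
    "sliding_windows",
    "compute_rmssd",
    "compute_mean_hr",
    "compute_std_acc",
    "compute_qi",
    "compute_window_features",
    "filter_windows",
    "hourly_aggregate",
    "coverage_filter",
    "night_subset",
    "NIGHT_HOURS",
]

#: wall-clock hours of the night analysis window, in time-index order
NIGHT_HOURS = (22, 23, 0, 1, 2, 3, 4, 5)


@dataclass
class BeatStream:
    """Per-participant beat annotations.

    ``t_ms`` strictly increasing timestamps (ms from recording start),
    ``rr_ms`` positive inter-beat intervals, ``morph_corr`` in [0, 1].
    """

    pid: str
    t_ms: np.ndarray
    rr_ms: np.ndarray
    morph_corr: np.ndarray
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2019-09-05 09:00"))

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.morph_corr = np.asarray(self.morph_corr, dtype=float)
        if self.t_ms.size and np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("beat timestamps must be strictly increasing")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")
        if np.any((self.morph_corr < 0) | (self.morph_corr > 1)):
            raise ValueError("morphology correlations must lie in [0, 1]")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def duration_s(self) -> float:
        return float(self.t_ms[-1] / 1000.0) if self.t_ms.size else 0.0


@dataclass
class AccTrace:
    """Acceleration-magnitude samples (g) on the same clock as the beats."""

    pid: str
    t_ms: np.ndarray
    mag_g: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.mag_g = np.asarray(self.mag_g, dtype=float)
        if self.t_ms.size and np.any(np.diff(self.t_ms) < 0):
            raise ValueError("accelerometer timestamps must be non-decreasing")
        if np.any(self.mag_g < 0):
            raise ValueError("acceleration magnitudes must be >= 0")


def compute_rmssd(rr) -> float:
    """Root mean square of successive RR differences (ms).

    Needs at least 3 beats (2 successive differences); otherwise NaN.
    """
    arr = np.asarray(rr, dtype=float)
    if arr.size < 3:
        return float("nan")
    d = np.diff(arr)
    return float(np.sqrt(np.mean(d * d)))


def compute_mean_hr(rr) -> float:
    """Beat-wise mean heart rate (bpm): mean of 60000 / RR_i."""
    arr = np.asarray(rr, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(np.mean(60000.0 / arr))


def compute_std_acc(mag) -> float:
    """Population SD of acceleration magnitude within a window (g)."""
    arr = np.asarray(mag, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(np.std(arr))


def compute_qi(t_ms, rr_ms, morph_corr, rules: QualityRules, window_s: float = 300.0,
               t0_ms: float = 0.0) -> float:
    """Rule-based signal-quality index of one window.

    The window is split into fixed sub-segments (default 10 s); a
    sub-segment passes iff (a) its implied HR lies within
    [hr_min, hr_max], (b) no RR interval exceeds ``max_rr_gap_s``,
    (c) max(RR)/min(RR) <= ``max_rr_ratio`` and (d) the mean morphology
    correlation is >= ``min_morph_corr``.  QI is the passing fraction;
    an empty window scores 0.
    """
    t = np.asarray(t_ms, dtype=float)
    if t.size == 0:
        return 0.0
    rr = np.asarray(rr_ms, dtype=float)
    mc = np.asarray(morph_corr, dtype=float)
    n_seg = max(1, int(round(window_s / rules.subsegment_s)))
    passing = 0
    for k in range(n_seg):
        lo = t0_ms + k * rules.subsegment_s * 1000.0
        hi = lo + rules.subsegment_s * 1000.0
        sel = (t >= lo) & (t < hi)
        if not sel.any():
            continue  # empty sub-segment: fails (not counted as pass)
        seg_rr = rr[sel]
        hr = 60000.0 / np.mean(seg_rr)
        ok = (
            rules.hr_min <= hr <= rules.hr_max
            and np.max(seg_rr) <= rules.max_rr_gap_s * 1000.0
            and np.max(seg_rr) / np.min(seg_rr) <= rules.max_rr_ratio
            and np.mean(mc[sel]) >= rules.min_morph_corr
        )
        passing += bool(ok)
    return passing / n_seg


def sliding_windows(stream: BeatStream, acc: AccTrace | None = None,
                    length_s: float = 300.0, step_s: float = 60.0) -> pd.DataFrame:
    """Enumerate window start/end times over a beat stream.

    Windows start at the stream start (t = 0), advance by ``step_s`` and
    any window extending past the last beat is discarded.  The default
    5-min/1-min stepping realises 4 min of overlap; ``step_s == length_s``
    gives the non-overlapping 1-min stress-task mode.
    """
    if not length_s >= step_s > 0:
        raise ValueError("need length_s >= step_s > 0")
    end = stream.duration_s
    rows = []
    k = 0
    while True:
        start = k * step_s
        if start + length_s > end + 1e-9:
            break
        rows.append((stream.pid, start, start + length_s))
        k += 1
    return pd.DataFrame(rows, columns=["pid", "start_s", "end_s"])


def compute_window_features(stream: BeatStream, acc: AccTrace | None,
                            rules: QualityRules | None = None,
                            length_s: float = 300.0, step_s: float = 60.0) -> pd.DataFrame:
    """Fill mean HR, RMSSD, Std Acc, QI and beat counts for every window."""
    rules = rules or QualityRules()
    win = sliding_windows(stream, acc, length_s=length_s, step_s=step_s)
    feats = []
    for _, row in win.iterrows():
        lo, hi = row["start_s"] * 1000.0, row["end_s"] * 1000.0
        sel = (stream.t_ms >= lo) & (stream.t_ms < hi)
        rr = stream.rr_ms[sel]
        n_beats = int(sel.sum())
        if acc is not None:
            asel = (acc.t_ms >= lo) & (acc.t_ms < hi)
            std_acc = compute_std_acc(acc.mag_g[asel])
        else:
            std_acc = float("nan")
        feats.append(
            {
                "mean_hr": compute_mean_hr(rr),
                "rmssd": compute_rmssd(rr),
                "std_acc": std_acc,
                "qi": compute_qi(
                    stream.t_ms[sel], rr, stream.morph_corr[sel], rules,
                    window_s=length_s, t0_ms=lo,
                ),
                "n_beats": n_beats,
            }
        )
    out = pd.concat([win, pd.DataFrame(feats, index=win.index)], axis=1)
    start = stream.start_time
    if len(out):
        stamps = start + pd.to_timedelta(out["start_s"], unit="s")
        out["clock_hour"] = stamps.dt.floor("h")
        out["hour_of_day"] = stamps.dt.hour
    else:
        out["clock_hour"] = pd.Series(dtype="datetime64[ns]")
        out["hour_of_day"] = pd.Series(dtype=int)
    return out


def filter_windows(windows: pd.DataFrame, qi_threshold: float = 0.8,
                   std_acc_threshold: float = 0.04) -> pd.DataFrame:
    """Apply the quality and activity exclusions.

    A window is retained iff QI >= ``qi_threshold`` AND Std Acc <=
    ``std_acc_threshold`` (boundaries inclusive: the published rules
    exclude QI *below* 0.8 and Std Acc *above* 0.04).  Adds ``retained``
    and ``exclusion_reason`` columns ('' | 'quality' | 'activity' |
    'quality+activity'); NaN Std Acc (no accelerometer) counts as quiet.
    """
    out = windows.copy()
    bad_qi = out["qi"].to_numpy() < qi_threshold
    std = out["std_acc"].to_numpy()
    bad_acc = np.where(np.isnan(std), False, std > std_acc_threshold)
    reason = np.full(len(out), "", dtype=object)
    reason[bad_qi] = "quality"
    reason[bad_acc] = "activity"
    reason[bad_qi & bad_acc] = "quality+activity"
    out["retained"] = ~(bad_qi | bad_acc)
    out["exclusion_reason"] = reason
    return out


def hourly_aggregate(windows: pd.DataFrame, min_windows: int = 5) -> pd.DataFrame:
    """Average retained windows into hourly records.

    Windows are assigned to the wall-clock hour of their *start*; a record
    is emitted only when at least ``min_windows`` retained windows back
    it.  Means are unweighted.
    """
    kept = windows[windows["retained"]] if "retained" in windows else windows
    if kept.empty:
        return pd.DataFrame(
            columns=["pid", "clock_hour", "hour_of_day", "mean_hr",
                     "mean_rmssd", "activity_index", "n_windows"]
        )
    grp = kept.groupby(["pid", "clock_hour"], sort=True)
    agg = grp.agg(
        hour_of_day=("hour_of_day", "first"),
        mean_hr=("mean_hr", "mean"),
        mean_rmssd=("rmssd", "mean"),
        activity_index=("std_acc", "mean"),
        n_windows=("mean_hr", "size"),
    ).reset_index()
    return agg[agg["n_windows"] >= min_windows].reset_index(drop=True)


def coverage_filter(hourly: pd.DataFrame) -> pd.DataFrame:
    """Keep only participants whose records cover all 24 clock hours.

    Coverage is over the whole recording without any within-day
    consecutiveness requirement: a participant is retained iff every
    ``hour_of_day`` 0-23 appears at least once.
    """
    if hourly.empty:
        return hourly.copy()
    ok = hourly.groupby("pid")["hour_of_day"].nunique() == 24
    keep = ok[ok].index
    return hourly[hourly["pid"].isin(keep)].reset_index(drop=True)


def night_subset(hourly: pd.DataFrame) -> pd.DataFrame:
    """Night records (22:00-05:00) with the linear time index 1..8.

    22:00 -> 1, 23:00 -> 2, 00:00 -> 3, ..., 05:00 -> 8; all other hours
    are dropped.
    """
    mapping = {h: i + 1 for i, h in enumerate(NIGHT_HOURS)}
    sel = hourly[hourly["hour_of_day"].isin(mapping)].copy()
    sel["time"] = sel["hour_of_day"].map(mapping).astype(int)
    return sel.reset_index(drop=True)
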