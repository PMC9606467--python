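"""Depression / chronic-stress group derivation and covariate recoding.

Depressive symptoms are dichotomised at the official DASS depression
cut-off of 6 (scores strictly above 6 count as high).  Chronic stress is
stratified from the PSS-10 either at cohort percentiles (75th/95th) or at
the fixed published cuts (18, 24): normative (pss <= cut1), high
(cut1 < pss <= cut2), extreme (pss > cut2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GroupAssignment",
    "dep_group",
    "pss_group",
    "assign_groups",
    "impute_median",
    "minmax_rescale",
    "activity_category",
    "ACTIVITY_BANDS",
]

DASSD_CUTOFF = 6
FIXED_PSS_CUTS = (18.0, 24.0)
STRESS_LEVELS = ("normative", "high", "extreme")

#: weekly sport-hours bands in ascending order -> ordinal codes 0..4
ACTIVITY_BANDS = ("0", "0-1h", "1-3h", "3-5h", ">5h")


@dataclass
class GroupAssignment:
    """Per-cohort group labels plus the PSS cuts actually used."""

    table: pd.DataFrame  # columns: pid, dep_group, stress_group
    pss_cuts: tuple[float, float]


def dep_group(dassd) -> np.ndarray | str:
    """Binary depressive-symptom group from a DASS-D total (0-21).

    Scores strictly above the cut-off of 6 are 'high'; 6 itself is 'low'.
    """
    arr = np.asarray(dassd)
    if np.any((arr < 0) | (arr > 21)):
        raise ValueError("DASS-D totals must lie in [0, 21]")
    out = np.where(arr > DASSD_CUTOFF, "high", "low")
    return out.item() if np.isscalar(dassd) else out


def pss_group(
    pss_scores, mode: str = "percentile", cuts: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Three-level chronic-stress group from PSS-10 totals.

    Parameters
    ----------
    pss_scores : array-like
        Cohort PSS totals (0-40).
    mode : {'percentile', 'fixed'}
        'percentile' derives the cuts as the 75th/95th percentile of the
        cohort (linear-interpolation quantile); 'fixed' uses (18, 24).
    cuts : optional explicit (cut1, cut2) override.

    Returns the per-subject labels and the cuts used.  Boundary reading:
    normative iff pss <= cut1, extreme iff pss > cut2.
    """
    arr = np.asarray(pss_scores, dtype=float)
    if arr.size == 0:
        raise ValueError("pss_scores must be non-empty")
    if cuts is None:
        if mode == "percentile":
            if arr.size < 20:
                warnings.warn(
                    "fewer than 20 subjects: the 95th-percentile cut is unstable",
                    stacklevel=2,
                )
            cuts = (float(np.quantile(arr, 0.75)), float(np.quantile(arr, 0.95)))
        elif mode == "fixed":
            cuts = FIXED_PSS_CUTS
        else:
            raise ValueError("mode must be 'percentile' or 'fixed'")
    cut1, cut2 = float(cuts[0]), float(cuts[1])
    if not cut1 < cut2:
        # degenerate score distributions collapse the strata
        cut2 = cut1
    labels = np.full(arr.shape, "normative", dtype=object)
    labels[arr > cut1] = "high"
    labels[arr > cut2] = "extreme"
    return labels, (cut1, cut2)


def assign_groups(cohort: pd.DataFrame, mode: str = "percentile") -> GroupAssignment:
    """Derive both groupings for a cohort table with pid/pss/dassd columns."""
    stress, cuts = pss_group(cohort["pss"].to_numpy(), mode=mode)
    table = pd.DataFrame(
        {
            "pid": cohort["pid"].to_numpy(),
            "dep_group": dep_group(cohort["dassd"].to_numpy()),
            "stress_group": stress,
        }
    )
    return GroupAssignment(table=table, pss_cuts=cuts)


def impute_median(values) -> np.ndarray:
    """Replace missing entries by the median of the observed entries."""
    arr = np.asarray(values, dtype=float)
    mask = np.isnan(arr)
    if mask.all():
        raise ValueError("cannot impute: all values are missing")
    out = arr.copy()
    out[mask] = np.median(arr[~mask])
    return out


def minmax_rescale(values) -> np.ndarray:
    """Rescale to [0, 1] via (x - min) / (max - min).

    A constant input maps to all zeros (with a warning) rather than
    dividing by zero.
    """
    arr = np.asarray(values, dtype=float)
    lo = np.nanmin(arr)
    hi = np.nanmax(arr)
    if hi == lo:
        warnings.warn("constant input to minmax_rescale; returning zeros", stacklevel=2)
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def activity_category(band) -> np.ndarray | int:
    """Map a weekly sport-hours band label to its ordinal code 0..4."""

    def one(label: str) -> int:
        key = str(label).strip().replace("–", "-").rstrip("h").rstrip()
        key = key.replace(" ", "")
        lookup = {"0": 0, "0-1": 1, "1-3": 2, "3-5": 3, ">5": 4}
        if key not in lookup:
            raise ValueError(f"unknown activity band {label!r}")
        return lookup[key]

    if isinstance(band, (str, bytes)):
        return one(band)
    return np.array([one(b) for b in band], dtype=int)
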