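"""Nonparametric group comparisons and descriptive moments.

The Table-1-style machinery: two-group comparisons use the Wilcoxon
rank-sum test (tie-corrected normal approximation), multi-group
comparisons Kruskal-Wallis followed — only when significant — by
pairwise Dunn z-tests with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contrasts import bh_adjust

__all__ = [
    "GroupComparison",
    "wilcoxon_rank_sum",
    "kruskal_dunn",
    "sample_moments",
    "describe_by",
]


@dataclass
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p: float
    posthoc: pd.DataFrame | None  # columns: pair, z, p_adj (None unless KW rejects)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test (Mann-Whitney form).

    Returns (W, p) with W the rank-sum-based U statistic of the first
    sample and a two-sided tie-corrected normal p-value.
    """
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _dunn(values: np.ndarray, labels: np.ndarray, alpha_entry: float) -> pd.DataFrame:
    """Pairwise Dunn z-tests on pooled ranks with tie correction."""
    ranks = sps.rankdata(values)
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    groups = pd.unique(labels)
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    n_g = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for a, b in combinations(groups, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / n_g[a] + 1.0 / n_g[b])
        )
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        rows.append({"pair": f"{a}-{b}", "z": float(z),
                     "p_raw": float(2 * sps.norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def kruskal_dunn(values, labels, variable: str = "", alpha: float = 0.05) -> GroupComparison:
    """Kruskal-Wallis test with BH-adjusted Dunn post-hocs when it rejects."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    samples = [values[labels == g] for g in pd.unique(labels)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if np.all(values == values[0]):
        stat, p = 0.0, 1.0  # fully constant data: KW statistic is 0 by convention
    else:
        stat, p = sps.kruskal(*samples)
    posthoc = _dunn(values, labels, alpha) if p < alpha else None
    return GroupComparison(
        variable=variable, test="kruskal", statistic=float(stat), p=float(p),
        posthoc=posthoc,
    )


def sample_moments(values) -> dict[str, float]:
    """Mean, SD, median, IQR, skewness (m3/m2^1.5) and non-excess kurtosis.

    Kurtosis is reported raw (normal = 3), the convention under which
    heavier-than-normal tails read as > 3.  Quantiles use the
    linear-interpolation rule.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no observed values")
    m = arr.mean()
    c = arr - m
    m2 = np.mean(c**2)
    skew = np.mean(c**3) / m2**1.5 if m2 > 0 else 0.0
    kurt = np.mean(c**4) / m2**2 if m2 > 0 else 0.0
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    return {
        "mean": float(m),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
        "iqr": float(q3 - q1),
        "skewness": float(skew),
        "kurtosis": float(kurt),
    }


def describe_by(cohort: pd.DataFrame, by: list[str], variables: list[str],
                alpha: float = 0.05) -> pd.DataFrame:
    """Per-group medians/IQRs plus the appropriate omnibus test per variable."""
    key = cohort[by].astype(str).agg("/".join, axis=1).to_numpy()
    rows = []
    for var in variables:
        vals = cohort[var].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        groups = pd.unique(key[ok])
        if len(groups) == 2:
            a, b = groups
            stat, p = wilcoxon_rank_sum(vals[ok][key[ok] == a], vals[ok][key[ok] == b])
            test = "wilcoxon"
            posthoc = None
        else:
            comp = kruskal_dunn(vals[ok], key[ok], variable=var, alpha=alpha)
            stat, p, test, posthoc = comp.statistic, comp.p, comp.test, comp.posthoc
        row = {"variable": var, "test": test, "statistic": stat, "p": p}
        for g in groups:
            sub = vals[ok][key[ok] == g]
            row[f"median[{g}]"] = float(np.median(sub))
            row[f"iqr[{g}]"] = float(np.subtract(*np.quantile(sub, [0.75, 0.25])))
        if posthoc is not None:
            sig = posthoc[posthoc["p_adj"] < alpha]["pair"].tolist()
            row["significant_pairs"] = ";".join(sig)
        rows.append(row)
    return pd.DataFrame(rows)
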