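"""Pairwise condition contrasts and false-discovery-rate adjustment.

Within a stratum of one grouping factor (e.g. the low-depressive-symptom
subjects), all 6 pairwise differences between the 4 stress-task
conditions are linear combinations of the fitted reactivity
coefficients; the other grouping factor is averaged over, by default
with its observed proportions as weights.  The 6 p-values of a stratum
form one Benjamini-Hochberg family.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import MIST_CONDITIONS
from .lmm import LmmFit

__all__ = ["bh_adjust", "pairwise_contrasts", "CONDITION_PAIRS"]

#: the 6 ordered condition pairs, later task phase minus earlier
CONDITION_PAIRS = tuple(
    (b, a) for a, b in combinations(MIST_CONDITIONS, 2)
)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def _contrast_vector(names, cond_hi, cond_lo, dep_w, stress_w):
    """L such that L'beta = E[log HR | cond_hi] - E[log HR | cond_lo].

    ``dep_w`` / ``stress_w`` are the effective values of the depression
    and chronic-stress dummies in the stratum (0/1 inside a stratum of
    that factor, a mixing weight for the averaged-over factor).
    """
    L = pd.Series(0.0, index=names)

    def add(cond, sign):
        if cond == "baseline":
            return
        L[f"cond[{cond}]"] += sign
        L[f"cond[{cond}]:dep[high]"] += sign * dep_w
        L[f"cond[{cond}]:stress[high]"] += sign * stress_w

    add(cond_hi, +1.0)
    add(cond_lo, -1.0)
    return L


def pairwise_contrasts(
    fit: LmmFit,
    stratify_by: str = "dep_group",
    stress_share: float = 0.5,
    dep_share: float = 0.5,
    weights: str = "proportional",
) -> pd.DataFrame:
    """All 6 condition contrasts per stratum of one grouping factor.

    Parameters
    ----------
    fit : the fitted reactivity model.
    stratify_by : 'dep_group' or 'stress_group'.
    stress_share, dep_share : observed shares of the high groups, used
        when ``weights == 'proportional'`` to average over the factor
        not stratified on; ``weights == 'equal'`` uses 0.5.
    """
    if weights not in ("proportional", "equal"):
        raise ValueError("weights must be 'proportional' or 'equal'")
    if stratify_by not in ("dep_group", "stress_group"):
        raise ValueError("stratify_by must be 'dep_group' or 'stress_group'")
    w_stress = stress_share if weights == "proportional" else 0.5
    w_dep = dep_share if weights == "proportional" else 0.5
    names = list(fit.params.index)
    cov = fit.cov_params.to_numpy()
    rows = []
    strata = ("low", "high") if stratify_by == "dep_group" else ("normative", "high")
    for stratum in strata:
        if stratify_by == "dep_group":
            dep_w = 1.0 if stratum == "high" else 0.0
            stress_w = w_stress
        else:
            dep_w = w_dep
            stress_w = 1.0 if stratum == "high" else 0.0
        stratum_rows = []
        for hi, lo in CONDITION_PAIRS:
            L = _contrast_vector(names, hi, lo, dep_w, stress_w)
            est = float(L @ fit.params)
            se = float(np.sqrt(L.to_numpy() @ cov @ L.to_numpy()))
            z = est / se if se > 0 else np.inf
            stratum_rows.append(
                {
                    "stratum": stratum,
                    "pair": f"{hi}-{lo}",
                    "estimate": est,
                    "se": se,
                    "p_raw": float(2 * stats.norm.sf(abs(z))),
                }
            )
        padj = bh_adjust([r["p_raw"] for r in stratum_rows])
        for r, pa in zip(stratum_rows, padj):
            r["p_adj"] = float(pa)
        rows.extend(stratum_rows)
    out = pd.DataFrame(rows)
    out.insert(0, "stratify_by", stratify_by)
    return out
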