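"""Backward stepwise model selection on AIC, respecting marginality.

The procedure mirrors buildmer-style "order, backward" selection: first
make sure a converging model exists, then repeatedly remove the single
term whose removal lowers the AIC the most, stopping when no removal
improves it.  Terms are removed as blocks (a harmonic sine/cosine pair
or a factor's dummy set goes jointly) and a term is only eligible while
no retained interaction depends on it.  Protected terms (the intercept,
anything the caller pins) are never candidates.  All comparison fits use
ML (AIC across fixed-effect structures is only meaningful under ML);
the returned final fit is refitted with REML.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .design import Term
from .lmm import LmmFit

__all__ = ["backward_stepwise", "droppable_terms"]


def droppable_terms(terms: list[Term], protected: tuple[str, ...] = ()) -> list[Term]:
    """Terms eligible for removal under marginality and protection."""
    present = {t.name for t in terms}
    out = []
    for t in terms:
        if t.protected or t.name in protected:
            continue
        if any(t.name in u.parents for u in terms if u.name in present and u is not t):
            continue
        out.append(t)
    return out


def backward_stepwise(
    terms: list[Term],
    fit_fun,
    protected: tuple[str, ...] = (),
) -> tuple[LmmFit, list[Term], pd.DataFrame]:
    """Run backward AIC elimination over a term list.

    Parameters
    ----------
    terms : initial (full) fixed-effect term list.
    fit_fun : callable(term_list, method) -> LmmFit; raises on failure.
    protected : extra term names that must never be removed.

    Returns (final REML fit, retained terms, trace).  The trace records
    one row per elimination round plus a final 'kept' row per survivor;
    its invariant is that no single eligible removal from the final
    model lowers the AIC.
    """
    current = list(terms)
    fit = fit_fun(current, "ml")
    if not fit.converged:
        warnings.warn("full model did not converge; selection continues from it",
                      stacklevel=2)
    rows = []
    while True:
        best_term, best_fit = None, None
        for t in droppable_terms(current, protected):
            cand = [u for u in current if u is not t]
            try:
                f = fit_fun(cand, "ml")
            except Exception:
                continue
            if not f.converged:
                continue
            if best_fit is None or f.aic < best_fit.aic:
                best_term, best_fit = t, f
        if best_fit is not None and best_fit.aic < fit.aic - 1e-9:
            rows.append(
                {"term": best_term.name, "action": "dropped",
                 "aic_before": fit.aic, "aic_after": best_fit.aic}
            )
            current = [u for u in current if u is not best_term]
            fit = best_fit
        else:
            break
    for t in current:
        rows.append({"term": t.name, "action": "kept",
                     "aic_before": fit.aic, "aic_after": fit.aic})
    final = fit_fun(current, "reml")
    trace = pd.DataFrame(rows, columns=["term", "action", "aic_before", "aic_after"])
    return final, current, trace
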