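"""Harmonic (cosinor) basis for circadian regression.

Heart rate is modelled on sine/cosine pairs with periods of 24, 12, 8
and 6 hours evaluated at the wall-clock hour of day, the standard
multi-component cosinor parameterisation: any single-period component
a*sin + b*cos is equivalent to an amplitude/acrophase pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import HARMONIC_NAMES, HARMONIC_PERIODS

__all__ = ["harmonic_design", "HARMONIC_NAMES", "HARMONIC_PERIODS"]


def harmonic_design(hour_of_day) -> pd.DataFrame:
    """Evaluate the 8 harmonic basis columns at (possibly fractional) hours.

    Columns are ordered sin24, cos24, sin12, cos12, sin8, cos8, sin6,
    cos6; every value lies in [-1, 1] and the basis is 24-h periodic.
    """
    t = np.atleast_1d(np.asarray(hour_of_day, dtype=float))
    cols = {}
    for period in HARMONIC_PERIODS:
        w = 2.0 * np.pi * t / period
        cols[f"sin{int(period)}"] = np.sin(w)
        cols[f"cos{int(period)}"] = np.cos(w)
    return pd.DataFrame(cols, columns=list(HARMONIC_NAMES))
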