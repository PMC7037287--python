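"""Analytical quality control: calibration lines, detection limits, recovery.

Detection and quantification limits follow the calibration-curve method:
``LoD = 3·SD/s`` and ``LoQ = 10·SD/s``, with ``s`` the fitted slope and
``SD`` the residual standard deviation of the calibration regression
(computed with the n−2 denominator of the residual standard error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CalibrationCurve:
    slope: float
    intercept: float
    resid_sd: float
    lod: float
    loq: float
    r_squared: float
    n: int


def fit_calibration(points) -> CalibrationCurve:
    """Ordinary least-squares line through (level, response) points.

    ``points`` is a sequence of pairs or a DataFrame with ``level`` and
    ``response`` columns.  Requires at least 3 distinct levels and a
    positive fitted slope (the limits are undefined otherwise).
    """
    if isinstance(points, pd.DataFrame):
        level = points["level"].to_numpy(dtype=float)
        response = points["response"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        level, response = arr[:, 0], arr[:, 1]
    if len(np.unique(level)) < 3:
        raise ValueError("calibration needs at least 3 distinct levels")

    fit = stats.linregress(level, response)
    if fit.slope <= 0:
        raise ValueError(f"non-positive calibration slope ({fit.slope:.4g}); limits undefined")
    resid = response - (fit.intercept + fit.slope * level)
    resid_sd = float(np.sqrt((resid ** 2).sum() / (len(level) - 2)))
    lod = 3.0 * resid_sd / fit.slope
    return CalibrationCurve(
        slope=float(fit.slope), intercept=float(fit.intercept),
        resid_sd=resid_sd, lod=lod, loq=(10.0 / 3.0) * lod,
        r_squared=float(fit.rvalue ** 2), n=len(level),
    )


def recovery_pct(measured: float, expected: float) -> float:
    """Spike recovery as a percentage of the expected concentration."""
    if expected <= 0:
        raise ValueError("expected concentration must be positive")
    return 100.0 * measured / expected
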