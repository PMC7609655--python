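"""Low-frequency growth-trend removal for ring-width series.

Ring widths carry age/size trends that would otherwise masquerade as
among-tree variance.  Each tree's earlywood and latewood width series is
detrended individually: a linear and a quadratic polynomial in calendar
year are fitted by least squares, the better model is chosen by AICc
(ties go to the linear model, by parsimony), and the detrended series is
the model residuals plus the series mean — so the mean annual growth of
the period is preserved exactly.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _ols_aicc(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    """Least-squares polynomial fit; returns (residuals, AICc).

    AICc uses the Gaussian log-likelihood with k counting the intercept,
    the ``degree`` slope coefficients and the residual variance.
    """
    n = len(y)
    # centre year to keep the Vandermonde well conditioned
    xc = x - x.mean()
    design = np.vander(xc, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    # floor relative to the data scale: an exact fit of either degree is
    # a tie, which the caller resolves in favour of the linear model
    sigma2 = max(rss / n, 1e-12 * (float(np.mean(y ** 2)) + 1e-300))
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = degree + 2
    if n - k - 1 <= 0:
        return resid, math.inf
    aicc = -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return resid, aicc


def detrend_series(years, widths) -> tuple[np.ndarray, int]:
    """Detrend one ring-width series; returns (detrended values, order).

    Fits degree-1 and degree-2 trends in year, picks the lower AICc
    (degree 1 on ties), and returns residuals plus the raw-series mean.
    Series shorter than 4 observations force the linear model with a
    warning; series too short for the quadratic AICc correction
    (n ≤ 5) fall back to linear as well.
    """
    years = np.asarray(years, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if len(years) != len(widths):
        raise ValueError("years and widths must have equal length")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")
    n = len(widths)
    if n < 2:
        return widths.copy(), 0

    if n < 4:
        logger.warning("series of length %d: linear trend forced", n)
        resid, _ = _ols_aicc(years, widths, 1)
        order = 1
    else:
        resid1, aicc1 = _ols_aicc(years, widths, 1)
        resid2, aicc2 = _ols_aicc(years, widths, 2)
        if aicc2 < aicc1:
            resid, order = resid2, 2
        else:
            resid, order = resid1, 1
    return resid + widths.mean(), order


def detrend_traits(traits: pd.DataFrame,
                   columns: tuple[str, ...] = ("EWW", "LWW")) -> pd.DataFrame:
    """Add detrended width columns to a ring-trait table.

    For each tree and each column, appends ``<col>_detrended`` and a
    ``trend_order_<col>`` column recording the chosen polynomial order.
    """
    out = traits.copy()
    for col in columns:
        out[f"{col}_detrended"] = np.nan
        out[f"trend_order_{col}"] = 0
    for tree, grp in traits.groupby("tree_id", sort=False):
        grp = grp.sort_values("year")
        for col in columns:
            vals, order = detrend_series(grp["year"].to_numpy(),
                                         grp[col].to_numpy())
            out.loc[grp.index, f"{col}_detrended"] = vals
            out.loc[grp.index, f"trend_order_{col}"] = order
    return out
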