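"""Small closed-form least-squares helpers used across the package."""

from __future__ import annotations

import numpy as np


def loglinear_rates(y: np.ndarray, times: np.ndarray):
    """Row-wise simple linear regression of ``y`` on ``times``.

    Parameters
    ----------
    y : ndarray, shape (n_rows, n_times) or (n_times,)
        Response values (typically log intensities).
    times : ndarray, shape (n_times,)

    Returns
    -------
    slope, intercept : ndarrays of shape (n_rows,)
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    t = np.asarray(times, dtype=float)
    tc = t - t.mean()
    denom = np.sum(tc * tc)
    if denom == 0:
        raise ValueError("need at least two distinct time points")
    slope = y @ tc / denom
    intercept = y.mean(axis=1) - slope * t.mean()
    return slope, intercept


def rsquared(y: np.ndarray, times: np.ndarray, slope: np.ndarray, intercept: np.ndarray):
    """R^2 of the row-wise linear fits; NaN where the response is constant."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    t = np.asarray(times, dtype=float)
    fitted = np.outer(slope, t) + intercept[:, None]
    ss_res = np.sum((y - fitted) ** 2, axis=1)
    ss_tot = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), np.nan)
    return r2
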