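"""Responsive-gene calling and spline-based response summaries.

A gene is *responsive* when its abundance ratio to t=0 exceeds 1.75-fold
(strictly) in either direction at any sampled time point.  The maximal fold
change is located on a cubic spline through the log2 profile (not-a-knot
boundary conditions, so polynomial profiles are reproduced exactly): the
candidate set is the interior roots of the spline derivative plus both
endpoints (a monotone response peaks at an endpoint, where the derivative
need not vanish), and the candidate with the largest absolute spline value
wins, ties broken by earliest time.  The *transience index* quantifies how
much of the maximal response has relaxed by the end of the course:
``1 - |log2fc(t_end)| / |max_fc|`` (1 = returned to baseline, 0 = fully
sustained).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 1.75
_TIE_RTOL = 1e-9


def call_responsive(matrix: ExpressionMatrix,
                    threshold: float = DEFAULT_FC_THRESHOLD) -> pd.Series:
    """Boolean per gene: any time point with linear fold change above threshold.

    The cutoff is applied on the linear ratio scale, symmetrically for
    induction and repression: responsive iff
    ``max_t max(ratio, 1/ratio) > threshold``, i.e. ``|log2fc| > log2(threshold)``.
    The inequality is strict — a peak ratio of exactly ``threshold`` is not
    responsive.
    """
    if matrix.scale != "log2_to_t0":
        raise ValueError("call_responsive expects a log2_to_t0 matrix")
    cut = math.log2(threshold)
    resp = np.nanmax(np.abs(matrix.values), axis=1) > cut
    return pd.Series(resp, index=pd.Index(matrix.gene_ids, name="gene_id"),
                     name="responsive")


def max_fold_change(profile, times) -> tuple[float, float]:
    """Signed maximal log2 change and its time, located on a cubic spline.

    Returns ``(max_fc, t_max)``.  Needs >= 4 points for the spline; on
    failure falls back to the discrete extremum with a logged warning.
    """
    y = np.asarray(profile, dtype=float)
    t = np.asarray(times, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    try:
        if t.size < 4:
            raise ValueError("cubic spline needs >= 4 time points")
        spline = CubicSpline(t, y, bc_type="not-a-knot")
        roots = spline.derivative().roots(extrapolate=False)
        roots = roots[np.isreal(roots)].real
        interior = roots[(roots > t[0]) & (roots < t[-1])]
        candidates = np.concatenate(([t[0]], np.sort(interior), [t[-1]]))
        values = spline(candidates)
    except ValueError as err:
        log.warning("spline failed (%s); falling back to discrete extremum", err)
        candidates, values = t, y
    best = np.max(np.abs(values))
    # earliest candidate whose |value| ties the maximum
    tie = np.abs(values) >= best * (1.0 - _TIE_RTOL)
    idx = int(np.argmax(tie))
    return float(values[idx]), float(candidates[idx])


def transience_index(profile, times, max_fc: float | None = None) -> float:
    """Fraction of the maximal response relaxed by the last time point.

    ``1 - |log2fc(t_end)| / |max_fc|``, clipped to [0, 1] (the spline
    extremum can slightly exceed the samples).  Undefined (NaN) when the
    maximal change is zero.
    """
    y = np.asarray(profile, dtype=float)
    t = np.asarray(times, dtype=float)
    if max_fc is None:
        max_fc, _ = max_fold_change(y, t)
    if max_fc == 0 or not np.isfinite(max_fc):
        return float("nan")
    end_value = y[np.argmax(t)]
    return float(np.clip(1.0 - abs(end_value) / abs(max_fc), 0.0, 1.0))


def profile_responses(matrix: ExpressionMatrix,
                      threshold: float = DEFAULT_FC_THRESHOLD) -> pd.DataFrame:
    """Per-gene response table: responsive flag, max_fc, t_max, transience."""
    responsive = call_responsive(matrix, threshold)
    rows = []
    for i, gene in enumerate(matrix.gene_ids):
        fc, t_max = max_fold_change(matrix.values[i], matrix.times)
        trans = transience_index(matrix.values[i], matrix.times, fc)
        rows.append((gene, bool(responsive.iloc[i]), fc, t_max, trans))
    return pd.DataFrame(
        rows, columns=["gene_id", "responsive", "max_fc", "t_max", "transience"]
    ).set_index("gene_id", drop=False)
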