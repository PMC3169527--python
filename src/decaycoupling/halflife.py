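"""First-order decay fitting, goodness-of-fit filtering, and stability changes.

Each zero-transformed decay profile is fitted to the first-order model
``m(t) = m0 * exp(-k t)``, which is exactly linear in log space:
``log2 m(t) = log2 m0 - (k / ln 2) t``.  The default fit is therefore an
ordinary least-squares line through the log2 profile with a free intercept
(absorbing t0 measurement noise); the decay constant is ``k = -slope * ln 2``
and the half-life ``t_half = ln 2 / k``.  Goodness of fit is the usual R^2
on the log2 values, and only genes exceeding a strict R^2 threshold
(default 0.9) enter downstream analyses.  A nonlinear least-squares variant
on the linear intensities is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ols import loglinear_rates, rsquared
from .containers import ExpressionMatrix

log = logging.getLogger(__name__)

LN2 = math.log(2.0)
DEFAULT_RSQ_THRESHOLD = 0.9


def fit_decay(profile, times, *, rsq_threshold: float = DEFAULT_RSQ_THRESHOLD,
              gene_id: str = "gene", strain: str = "wild_type",
              condition: str = "reference") -> pd.Series:
    """Fit a single log2-to-t0 decay profile; returns one half-life record.

    Requires at least 3 finite points.  A non-positive decay constant yields
    an infinite half-life and a failed record; a zero-variance profile has
    undefined R^2 and also fails.
    """
    y = np.asarray(profile, dtype=float)
    t = np.asarray(times, dtype=float)
    finite = np.isfinite(y)
    if finite.sum() < 3:
        raise ValueError("fit_decay needs at least 3 finite time points")
    y, t = y[finite], t[finite]
    slope, intercept = loglinear_rates(y, t)
    r2 = rsquared(y, t, slope, intercept)
    rec = _records_from_fits(
        [gene_id], slope, r2, rsq_threshold, strain, condition
    ).iloc[0]
    return rec


def _records_from_fits(gene_ids, slopes, r2, rsq_threshold, strain, condition
                       ) -> pd.DataFrame:
    slopes = np.atleast_1d(slopes)
    r2 = np.atleast_1d(r2)
    k = -slopes * LN2
    with np.errstate(divide="ignore"):
        halflife = np.where(k > 0, LN2 / np.where(k > 0, k, 1.0), np.inf)
    passed = np.where(np.isfinite(r2), r2 > rsq_threshold, False) & (k > 0)
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "k": k,
            "halflife": halflife,
            "r_squared": r2,
            "passed": passed,
            "strain": strain,
            "condition": condition,
        }
    ).set_index("gene_id", drop=False)


class ExponentialDecayModel:
    """First-order decay model over every gene of a zero-transformed matrix.

    Examples
    --------
    >>> from decaycoupling.containers import ExpressionMatrix
    >>> times = [0, 5, 10, 20, 30, 40, 50]
    >>> vals = [[-t / 10 for t in times]]   # half-life exactly 10 min
    >>> mat = ExpressionMatrix(["g1"], times, vals, scale="log2_to_t0")
    >>> res = ExponentialDecayModel(mat).fit()
    >>> float(res.records.loc["g1", "halflife"])
    10.0
    """

    def __init__(self, matrix: ExpressionMatrix):
        if matrix.scale != "log2_to_t0":
            raise ValueError("ExponentialDecayModel expects a log2_to_t0 matrix "
                             "(run normalize.zero_transform first)")
        if matrix.times.size < 3:
            raise ValueError("need at least 3 time points")
        self.matrix = matrix

    def fit(self, rsq_threshold: float = DEFAULT_RSQ_THRESHOLD,
            method: str = "ols") -> "DecayResults":
        """Fit every gene; ``method`` is "ols" (log-linear) or "nls"."""
        mat = self.matrix
        if method == "ols":
            slope, intercept = loglinear_rates(mat.values, mat.times)
            r2 = rsquared(mat.values, mat.times, slope, intercept)
        elif method == "nls":
            slope, r2 = self._fit_nls()
        else:
            raise ValueError(f"unknown method {method!r}")
        records = _records_from_fits(
            mat.gene_ids, slope, r2, rsq_threshold, mat.strain, mat.condition
        )
        return DecayResults(self, records, rsq_threshold, method)

    def _fit_nls(self):
        """Per-gene nonlinear fit of a*2^(slope*t) to the linear ratios."""
        from scipy.optimize import curve_fit

        mat = self.matrix
        t = mat.times
        slopes = np.empty(mat.n_genes)
        r2 = np.empty(mat.n_genes)
        for i in range(mat.n_genes):
            ratios = 2.0 ** mat.values[i]
            s0, _ = loglinear_rates(mat.values[i], t)
            try:
                popt, _ = curve_fit(
                    lambda tt, a, s: a * 2.0 ** (s * tt), t, ratios,
                    p0=[1.0, float(s0[0])], maxfev=5000,
                )
                slopes[i] = popt[1]
                fitted = popt[0] * 2.0 ** (popt[1] * t)
            except RuntimeError:  # pragma: no cover - pathological profiles
                slopes[i] = np.nan
                fitted = np.full_like(t, np.nan)
            # goodness of fit reported on the log2 scale for comparability
            with np.errstate(divide="ignore", invalid="ignore"):
                ylog = mat.values[i]
                flog = np.log2(np.maximum(fitted, 1e-300))
            ss_res = np.nansum((ylog - flog) ** 2)
            ss_tot = np.sum((ylog - ylog.mean()) ** 2)
            r2[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return slopes, r2


@dataclass
class DecayResults:
    """Fitted half-life records for one matrix plus the pass/fail filter."""

    model: ExponentialDecayModel
    records: pd.DataFrame
    rsq_threshold: float
    method: str

    @property
    def passed(self) -> pd.DataFrame:
        return self.records[self.records["passed"]]

    @property
    def pass_fraction(self) -> float:
        return float(self.records["passed"].mean())

    def summary(self) -> str:
        rec = self.records
        lines = [
            "Exponential decay fit" + f" (method={self.method})",
            f"  genes fitted:        {len(rec)}",
            f"  R^2 > {self.rsq_threshold:g} passed:    {int(rec['passed'].sum())} "
            f"({100 * self.pass_fraction:.1f}%)",
            f"  median half-life:    {rec.loc[rec['passed'], 'halflife'].median():.2f} min",
            f"  strain / condition:  {self.model.matrix.strain} / "
            f"{self.model.matrix.condition}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def filter_fits(records: pd.DataFrame, threshold: float = DEFAULT_RSQ_THRESHOLD):
    """Apply the strict R^2 filter; returns (passed records, report dict).

    The inequality is strict: a gene at exactly the threshold is excluded.
    """
    finite = np.isfinite(records["r_squared"].to_numpy(dtype=float))
    mask = finite & (records["r_squared"].to_numpy(dtype=float) > threshold) \
        & (records["k"].to_numpy(dtype=float) > 0)
    passed = records[mask]
    report = {
        "n_total": int(len(records)),
        "n_passed": int(mask.sum()),
        "pass_fraction": float(mask.mean()) if len(records) else float("nan"),
        "threshold": threshold,
    }
    return passed, report


def stability_change(ref_records: pd.DataFrame, stress_records: pd.DataFrame
                     ) -> pd.DataFrame:
    """Per-gene stability change: delta = log2(HL_stress / HL_reference).

    Only genes passing the fit filter in *both* conditions are kept; the
    number excluded from each side is logged.
    """
    ref = ref_records[ref_records["passed"]]
    stress = stress_records[stress_records["passed"]]
    common = ref.index.intersection(stress.index)
    n_dropped = len(ref_records.index.union(stress_records.index)) - len(common)
    if n_dropped:
        log.info("stability_change: %d gene(s) lacked a passing fit in one condition",
                 n_dropped)
    delta = np.log2(stress.loc[common, "halflife"] / ref.loc[common, "halflife"])
    return pd.DataFrame({"gene_id": common, "delta": delta.to_numpy()}).set_index(
        "gene_id", drop=False
    )
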