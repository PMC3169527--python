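"""Production-degradation coupling statistics.

The headline analysis asks, gene by gene, whether the change in mRNA
stability under stress (``delta`` = log2 stress/reference half-life ratio)
co-varies with the transcriptional response (signed maximal log2 abundance
change).  Under counter-action coupling the association is negative: induced
genes are destabilized, repressed genes stabilized.  Three views are
provided: an OLS fit with confidence intervals and Pearson correlation
(scatter view), a fold-enrichment 2x2 table over discretized classes
(induced/repressed x stabilized/destabilized), and the basal strain
comparison relating between-strain abundance differences to between-strain
half-life differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import spike_in_normalize

DEFAULT_FC_THRESHOLD = 1.75
DEFAULT_HL_THRESHOLD = 1.5

#: floor on reported p-values so -log10(p) stays finite
_P_FLOOR = 1e-300


@dataclass
class CouplingResults:
    """OLS fit of stability change on maximal fold change, with 95% CIs."""

    n_genes: int
    pearson_r: float
    neg_log10_p: float
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]

    def summary(self) -> str:
        s_lo, s_hi = self.slope_ci95
        i_lo, i_hi = self.intercept_ci95
        return "\n".join([
            "Coupling fit (stability change ~ maximal fold change)",
            f"  n genes:      {self.n_genes}",
            f"  Pearson r:    {self.pearson_r:.4f}   -log10(p) = {self.neg_log10_p:.2f}",
            f"  fitted line:  y = {self.slope:.4f}x + {self.intercept:+.4f}",
            f"  slope 95% CI:     ({s_lo:.4f}, {s_hi:.4f})",
            f"  intercept 95% CI: ({i_lo:.4f}, {i_hi:.4f})",
        ])

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "pearson_r": self.pearson_r,
            "neg_log10_p": self.neg_log10_p,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci95": list(self.slope_ci95),
            "intercept_ci95": list(self.intercept_ci95),
        }


class CouplingModel:
    """OLS model of y (stability change) on x (maximal fold change).

    Built either from two aligned vectors or with :meth:`from_tables` from
    the stability-change and response tables, restricted to an optional
    responsive mask.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        self.x, self.y = x[ok], y[ok]
        if self.x.size < 3:
            raise ValueError("coupling fit needs at least 3 finite pairs")

    @classmethod
    def from_tables(cls, stability: pd.DataFrame, responses: pd.DataFrame,
                    responsive_only: bool = False) -> "CouplingModel":
        resp = responses
        if responsive_only:
            resp = responses[responses["responsive"]]
        common = stability.index.intersection(resp.index)
        return cls(resp.loc[common, "max_fc"], stability.loc[common, "delta"])

    def fit(self) -> CouplingResults:
        import statsmodels.api as sm

        exog = sm.add_constant(self.x)
        res = sm.OLS(self.y, exog).fit()
        ci = res.conf_int(alpha=0.05)
        if self.x.std() == 0 or self.y.std() == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(self.x, self.y)
        neg_log_p = -math.log10(max(p, _P_FLOOR)) if np.isfinite(p) else float("nan")
        return CouplingResults(
            n_genes=int(self.x.size),
            pearson_r=float(r),
            neg_log10_p=neg_log_p,
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
            intercept_ci95=(float(ci[0, 0]), float(ci[0, 1])),
        )


def coupling_fit(stability_changes, max_fold_changes, responsive_mask=None
                 ) -> CouplingResults:
    """Functional wrapper: OLS of stability change on maximal fold change."""
    x = np.asarray(max_fold_changes, dtype=float)
    y = np.asarray(stability_changes, dtype=float)
    if responsive_mask is not None:
        mask = np.asarray(responsive_mask, dtype=bool)
        x, y = x[mask], y[mask]
    return CouplingModel(x, y).fit()


# ---------------------------------------------------------------------------
# discretized view: classification and fold enrichment
# ---------------------------------------------------------------------------

def classify_changes(max_fold_changes, stability_changes,
                     fc_threshold: float = DEFAULT_FC_THRESHOLD,
                     hl_threshold: float = DEFAULT_HL_THRESHOLD) -> pd.DataFrame:
    """Label each gene on both axes.

    abundance: induced iff ``max_fc > log2(fc_threshold)``, repressed iff
    ``max_fc < -log2(fc_threshold)``, else neutral.  stability: stabilized
    iff ``delta > log2(hl_threshold)``, destabilized iff
    ``delta < -log2(hl_threshold)``, else unchanged.
    """
    x = np.asarray(max_fold_changes, dtype=float)
    d = np.asarray(stability_changes, dtype=float)
    fc_cut = math.log2(fc_threshold)
    hl_cut = math.log2(hl_threshold)
    abundance = np.where(x > fc_cut, "induced",
                         np.where(x < -fc_cut, "repressed", "neutral"))
    stability = np.where(d > hl_cut, "stabilized",
                         np.where(d < -hl_cut, "destabilized", "unchanged"))
    return pd.DataFrame({"abundance_class": abundance, "stability_class": stability})


@dataclass
class FoldEnrichmentTable:
    """Observed/expected co-occurrence of abundance and stability classes.

    For each cell (abundance group g, stability category c):
    ``expected = (genome-wide fraction in c) * |g|`` and
    ``enrichment = observed / expected`` — the independence null.  A
    hypergeometric tail probability per cell is reported as auxiliary
    evidence.
    """

    cells: pd.DataFrame
    n_genes: int
    thresholds: dict = field(default_factory=dict)

    def enrichment(self, abundance_class: str, stability_class: str) -> float:
        row = self.cells[
            (self.cells["abundance_class"] == abundance_class)
            & (self.cells["stability_class"] == stability_class)
        ]
        return float(row["enrichment"].iloc[0])

    def summary(self) -> str:
        lines = ["Fold enrichment (observed / expected under independence)",
                 f"  n genes: {self.n_genes}"]
        for _, row in self.cells.iterrows():
            enr = "undefined" if not np.isfinite(row["enrichment"]) else f"{row['enrichment']:.2f}"
            lines.append(
                f"  {row['abundance_class']:>9} & {row['stability_class']:<12} "
                f"obs {int(row['observed']):>4}  exp {row['expected']:7.2f}  "
                f"enrichment {enr}  p = {row['p_hypergeom']:.3g}"
            )
        return "\n".join(lines)


def fold_enrichment(labels: pd.DataFrame, thresholds: dict | None = None
                    ) -> FoldEnrichmentTable:
    """Fold-enrichment table over the four informative cells.

    ``labels`` must cover the full gene set entering the analysis (the
    genome-wide fractions are computed from it).
    """
    n = len(labels)
    rows = []
    for a_cls in ("induced", "repressed"):
        group = labels["abundance_class"] == a_cls
        group_size = int(group.sum())
        for s_cls in ("stabilized", "destabilized"):
            in_cat = labels["stability_class"] == s_cls
            k_cat = int(in_cat.sum())
            observed = int((group & in_cat).sum())
            expected = (k_cat / n) * group_size if n else float("nan")
            if group_size == 0 or expected == 0:
                enrichment = float("nan")
            else:
                enrichment = observed / expected
            # over-representation tail: P[X >= observed] drawing group_size
            # genes from n with k_cat marked
            p = float(stats.hypergeom.sf(observed - 1, n, k_cat, group_size))
            rows.append((a_cls, s_cls, observed, expected, enrichment, p))
    cells = pd.DataFrame(
        rows, columns=["abundance_class", "stability_class", "observed",
                       "expected", "enrichment", "p_hypergeom"],
    )
    return FoldEnrichmentTable(cells, n, thresholds or {})


# ---------------------------------------------------------------------------
# basal strain comparison
# ---------------------------------------------------------------------------

@dataclass
class BasalComparison:
    """Between-strain basal comparison: abundance shift vs stability shift."""

    table: pd.DataFrame  # per-gene x (log2 abundance ratio), y (log2 HL ratio)
    fit: CouplingResults | None
    median_abundance_shift: float

    def summary(self) -> str:
        out = [
            "Basal mutant-vs-wild-type comparison",
            f"  n genes: {len(self.table)}",
            f"  median log2 abundance ratio (mut/wt): {self.median_abundance_shift:.4f}",
        ]
        if self.fit is not None:
            out.append("  " + self.fit.summary().replace("\n", "\n  "))
        return "\n".join(out)


def basal_comparison(wt_t0, mut_t0, wt_spike: float, mut_spike: float,
                     wt_ref_hl: pd.Series, mut_ref_hl: pd.Series,
                     gene_ids=None) -> BasalComparison:
    """Relate basal abundance differences to basal stability differences.

    ``wt_t0``/``mut_t0`` are the raw t=0 intensity arrays (one array each);
    they are spike-in normalized onto a common scale before the per-gene
    ratio is taken.  ``x = log2(mut/wt abundance)``, ``y = log2(mut/wt
    reference half-life)``; genes missing a passing half-life in either
    strain are excluded.  Returns the scatter table, an OLS fit of y on x
    (None when degenerate), and the genome-wide median abundance shift.
    """
    wt_t0 = np.asarray(wt_t0, dtype=float)
    mut_t0 = np.asarray(mut_t0, dtype=float)
    if gene_ids is None:
        gene_ids = list(wt_ref_hl.index)
    norm = spike_in_normalize(
        np.column_stack([wt_t0, mut_t0]), [wt_spike, mut_spike]
    )
    frame = pd.DataFrame(
        {"x": np.log2(norm[:, 1] / norm[:, 0])}, index=pd.Index(gene_ids, name="gene_id")
    )
    hl = pd.concat([wt_ref_hl.rename("wt"), mut_ref_hl.rename("mut")], axis=1).dropna()
    hl = hl[np.isfinite(hl["wt"]) & np.isfinite(hl["mut"])]
    common = frame.index.intersection(hl.index)
    table = frame.loc[common].copy()
    table["y"] = np.log2(hl.loc[common, "mut"] / hl.loc[common, "wt"])
    fit = None
    if len(table) >= 3 and table["x"].std() > 0 and table["y"].std() > 0:
        fit = CouplingModel(table["x"], table["y"]).fit()
    return BasalComparison(
        table=table,
        fit=fit,
        median_abundance_shift=float(frame["x"].median()),
    )
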