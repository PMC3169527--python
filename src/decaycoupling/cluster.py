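"""Clustering of concatenated two-strain response profiles.

Responsive genes are represented by the concatenation of their wild-type and
mutant log2 abundance profiles; pairwise distance is one minus the Spearman
rank correlation between those feature vectors, and genes are agglomerated
by average linkage.  The tree is cut to a fixed number of clusters
(default 3).  Per cluster, the mutant's stress stability change is regressed
on the wild type's: a slope whose 95% confidence interval lies entirely
below 1 flags an impaired ability of the mutant to modulate stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


def spearman_distance_matrix(features: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman correlation between rows; values in [0, 2]."""
    ranks = np.apply_along_axis(rankdata, 1, np.asarray(features, dtype=float))
    corr = np.corrcoef(ranks)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


@dataclass
class ClusterResult:
    """Assignments, linkage, and per-cluster mean profiles."""

    gene_ids: list[str]
    assignments: pd.Series  # labels 1..k
    k: int
    linkage: np.ndarray
    cluster_means: dict = field(default_factory=dict)  # (cluster, strain) -> profile
    excluded: list[str] = field(default_factory=list)

    def members(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])

    def to_newick(self) -> str:
        """Dendrogram in Newick format with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)
        labels = self.gene_ids

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def cluster_profiles(wt: ExpressionMatrix, mut: ExpressionMatrix,
                     responsive_mask: pd.Series, k: int = 3,
                     *, sd_normalize: bool = False) -> ClusterResult:
    """Cluster concatenated WT+mutant profiles of responsive genes.

    Genes with a constant concatenated profile (undefined Spearman
    correlation) are excluded with a warning.  ``sd_normalize`` divides each
    gene's concatenated profile by its standard deviation before computing
    cluster means (display aid; distances are rank-based and unaffected).
    Cluster labels are deterministic: clusters are numbered 1..k by the
    order of first appearance along the gene list.
    """
    if wt.gene_ids != mut.gene_ids:
        raise ValueError("wild-type and mutant matrices must share gene order")
    resp_ids = [g for g in wt.gene_ids if bool(responsive_mask.get(g, False))]
    if len(resp_ids) < k:
        raise ValueError(f"need at least k={k} responsive genes, got {len(resp_ids)}")
    wt_sub = wt.select_genes(resp_ids)
    mut_sub = mut.select_genes(resp_ids)
    features = np.hstack([wt_sub.values, mut_sub.values])

    constant = np.all(features == features[:, [0]], axis=1)
    if constant.any():
        log.warning("cluster_profiles: excluding %d constant profile(s)",
                    int(constant.sum()))
    keep_ids = [g for g, c in zip(resp_ids, constant) if not c]
    excluded = [g for g, c in zip(resp_ids, constant) if c]
    features = features[~constant]

    dist = spearman_distance_matrix(features)
    condensed = dist[np.triu_indices(len(keep_ids), k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # renumber by order of first appearance for input-order stability
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]

    assignments = pd.Series(labels, index=pd.Index(keep_ids, name="gene_id"),
                            name="cluster")
    profiles = features.copy()
    if sd_normalize:
        sd = profiles.std(axis=1, keepdims=True)
        profiles = profiles / np.where(sd > 0, sd, 1.0)
    n_t = wt_sub.times.size
    means = {}
    for c in range(1, int(labels.max()) + 1):
        sel = labels == c
        means[(c, "wild_type")] = profiles[sel, :n_t].mean(axis=0)
        means[(c, "mutant")] = profiles[sel, n_t:].mean(axis=0)
    return ClusterResult(keep_ids, assignments, k, linkage, means, excluded)


@dataclass
class ClusterSlopeFit:
    """Per-cluster OLS of mutant stability change on wild-type stability change."""

    cluster: int
    n_genes: int
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    impaired: bool  # slope 95% CI entirely below 1

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "n_genes": self.n_genes,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci95": list(self.slope_ci95),
            "impaired": self.impaired,
        }


def cluster_stability_slopes(result: ClusterResult,
                             wt_stability: pd.DataFrame,
                             mut_stability: pd.DataFrame) -> list[ClusterSlopeFit]:
    """Fit mutant delta ~ wild-type delta per cluster.

    Orientation: x = wild type, y = mutant, so a slope below 1 means the
    mutant modulates stability less than the wild type for those genes.
    Clusters with fewer than 3 usable genes are skipped (reported in the
    log).
    """
    import statsmodels.api as sm

    fits = []
    for c in sorted(result.assignments.unique()):
        ids = result.assignments.index[result.assignments == c]
        common = wt_stability.index.intersection(mut_stability.index).intersection(ids)
        if len(common) < 3:
            log.warning("cluster %d: only %d usable gene(s); fit skipped",
                        c, len(common))
            continue
        x = wt_stability.loc[common, "delta"].to_numpy()
        y = mut_stability.loc[common, "delta"].to_numpy()
        res = sm.OLS(y, sm.add_constant(x)).fit()
        ci = res.conf_int(alpha=0.05)
        fits.append(ClusterSlopeFit(
            cluster=int(c),
            n_genes=int(len(common)),
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
            impaired=bool(ci[1, 1] < 1.0),
        ))
    return fits
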