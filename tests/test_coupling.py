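"""Tests for coupling fits, classification, fold enrichment, basal comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decaycoupling.coupling import (
    CouplingModel,
    basal_comparison,
    classify_changes,
    coupling_fit,
    fold_enrichment,
)


class TestCouplingFit:
    def test_perfect_anticorrelation_recovers_slope_minus_one(self, rng):
        x = rng.normal(size=30)
        res = coupling_fit(-x, x)
        assert res.slope == pytest.approx(-1.0, abs=1e-12)
        assert res.pearson_r == pytest.approx(-1.0, abs=1e-12)
        assert res.slope_ci95[0] == pytest.approx(-1.0, abs=1e-9)
        assert res.slope_ci95[1] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_normals_show_no_coupling(self, rng):
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        res = coupling_fit(y, x)
        assert abs(res.pearson_r) < 0.1
        assert res.slope_ci95[0] < 0 < res.slope_ci95[1]

    def test_matches_normal_equation_solution(self, rng):
        x = rng.normal(size=200)
        y = -0.8 * x + rng.normal(scale=0.3, size=200)
        res = coupling_fit(y, x)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)

    def test_responsive_mask_restricts_the_fit(self, rng):
        x = np.concatenate([rng.normal(size=50), np.full(50, 100.0)])
        y = np.concatenate([-x[:50], np.zeros(50)])
        mask = np.arange(100) < 50
        res = coupling_fit(y, x, responsive_mask=mask)
        assert res.n_genes == 50
        assert res.slope == pytest.approx(-1.0, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            coupling_fit([1.0, 2.0], [1.0, 2.0])

    def test_ci_contains_point_estimate(self, rng):
        x = rng.normal(size=100)
        y = -x + rng.normal(scale=0.5, size=100)
        res = coupling_fit(y, x)
        assert res.slope_ci95[0] <= res.slope <= res.slope_ci95[1]
        assert res.intercept_ci95[0] <= res.intercept <= res.intercept_ci95[1]

    def test_summary_prints_fitted_line(self, rng):
        x = rng.normal(size=50)
        text = coupling_fit(-x, x).summary()
        assert "y = " in text and "95% CI" in text


class TestClassifyChanges:
    def test_example_labels(self):
        labels = classify_changes([1.5], [-1.0], fc_threshold=1.75, hl_threshold=1.5)
        assert labels.loc[0, "abundance_class"] == "induced"
        assert labels.loc[0, "stability_class"] == "destabilized"

    def test_origin_is_neutral_unchanged(self):
        labels = classify_changes([0.0], [0.0], 1.75, 1.5)
        assert labels.loc[0, "abundance_class"] == "neutral"
        assert labels.loc[0, "stability_class"] == "unchanged"

    def test_thresholds_are_on_linear_scale(self):
        # max_fc exactly at log2(threshold) is not induced (strict)
        labels = classify_changes([np.log2(1.75)], [np.log2(1.5)], 1.75, 1.5)
        assert labels.loc[0, "abundance_class"] == "neutral"
        assert labels.loc[0, "stability_class"] == "unchanged"


class TestFoldEnrichment:
    def build_labels(self, n, induced, destab, both):
        """n genes; `induced` induced, `destab` destabilized, `both` overlap."""
        abundance = np.array(["neutral"] * n, dtype=object)
        stability = np.array(["unchanged"] * n, dtype=object)
        abundance[:induced] = "induced"
        stability[:both] = "destabilized"
        stability[induced:induced + destab - both] = "destabilized"
        return pd.DataFrame({"abundance_class": abundance,
                             "stability_class": stability})

    def test_caption_formula_arithmetic(self):
        # 100 genes, 20 induced, 30 destabilized genome-wide, 12 overlap
        # -> expected 20 * 30/100 = 6, enrichment 2.0
        table = fold_enrichment(self.build_labels(100, 20, 30, 12))
        cell = table.cells[(table.cells.abundance_class == "induced")
                           & (table.cells.stability_class == "destabilized")]
        assert cell["expected"].iloc[0] == pytest.approx(6.0)
        assert cell["enrichment"].iloc[0] == pytest.approx(2.0)

    def test_full_overlap_enrichment_is_inverse_genome_fraction(self):
        # every induced gene destabilized -> enrichment = 1 / destab fraction
        table = fold_enrichment(self.build_labels(200, 40, 40, 40))
        assert table.enrichment("induced", "destabilized") == pytest.approx(
            1 / (40 / 200)
        )

    def test_independent_labels_show_no_enrichment(self, rng):
        n = 1000
        labels = pd.DataFrame({
            "abundance_class": rng.choice(
                ["induced", "repressed", "neutral"], size=n, p=[0.3, 0.3, 0.4]),
            "stability_class": rng.choice(
                ["stabilized", "destabilized", "unchanged"], size=n,
                p=[0.3, 0.3, 0.4]),
        })
        table = fold_enrichment(labels)
        assert np.all(table.cells["enrichment"].between(0.7, 1.4))
        assert np.all(table.cells["p_hypergeom"] > 0.01)

    def test_empty_group_reports_missing_enrichment(self):
        labels = self.build_labels(50, 0, 10, 0)
        table = fold_enrichment(labels)
        assert np.isnan(table.enrichment("induced", "destabilized"))

    def test_against_brute_force_contingency_and_hypergeometric(self, rng):
        # exact cross-check on random small instances (<= 50 genes)
        for _ in range(20):
            n = int(rng.integers(8, 51))
            labels = pd.DataFrame({
                "abundance_class": rng.choice(
                    ["induced", "repressed", "neutral"], size=n),
                "stability_class": rng.choice(
                    ["stabilized", "destabilized", "unchanged"], size=n),
            })
            table = fold_enrichment(labels)
            for _, row in table.cells.iterrows():
                group = labels["abundance_class"] == row["abundance_class"]
                cat = labels["stability_class"] == row["stability_class"]
                observed = 0
                for g, c in zip(group, cat):  # brute-force count
                    observed += int(g and c)
                assert row["observed"] == observed
                expected = group.sum() * cat.sum() / n
                assert row["expected"] == pytest.approx(expected)
                p = stats.hypergeom.sf(observed - 1, n, int(cat.sum()),
                                       int(group.sum()))
                assert row["p_hypergeom"] == pytest.approx(p, rel=1e-12)
                if group.sum() and expected > 0:
                    assert row["enrichment"] == pytest.approx(observed / expected)


class TestBasalComparison:
    def test_identical_strains_give_zero_shift_and_zero_spread(self):
        t0 = np.array([50.0, 100.0, 200.0])
        hl = pd.Series([10.0, 20.0, 30.0], index=["g0", "g1", "g2"])
        res = basal_comparison(t0, t0, 80.0, 80.0, hl, hl,
                               gene_ids=["g0", "g1", "g2"])
        assert res.median_abundance_shift == 0.0
        np.testing.assert_allclose(res.table["x"], 0.0)
        np.testing.assert_allclose(res.table["y"], 0.0)
        assert res.fit is None  # degenerate scatter has no meaningful fit

    def test_spike_normalization_removes_array_scale(self, rng):
        wt = rng.lognormal(4, 1, 300)
        mut = 0.7 * wt
        genes = [f"g{i}" for i in range(300)]
        hl = pd.Series(rng.uniform(10, 40, 300), index=genes)
        # mutant array measured at 3x overall gain, spike-in sees the same
        res = basal_comparison(wt, 3.0 * mut, 80.0, 240.0, hl, hl, gene_ids=genes)
        assert res.median_abundance_shift == pytest.approx(np.log2(0.7), abs=1e-9)

    def test_permuted_stability_decouples_the_fit(self, rng):
        n = 400
        genes = [f"g{i}" for i in range(n)]
        wt = rng.lognormal(4, 0.8, n)
        mut = wt * 2.0 ** rng.normal(-0.5, 0.3, n)
        hl_wt = pd.Series(rng.uniform(10, 40, n), index=genes)
        hl_mut = pd.Series(hl_wt.to_numpy() * 2.0 ** rng.normal(0, 0.3, n),
                           index=genes)
        perm = rng.permutation(n)
        res = basal_comparison(wt, mut, 80.0, 80.0, hl_wt,
                               pd.Series(hl_mut.to_numpy()[perm], index=genes),
                               gene_ids=genes)
        assert res.fit.slope_ci95[0] < 0 < res.fit.slope_ci95[1]

    def test_genes_missing_a_half_life_are_excluded(self):
        t0 = np.array([10.0, 20.0, 30.0, 40.0])
        genes = ["g0", "g1", "g2", "g3"]
        hl_wt = pd.Series([10.0, 15.0, 20.0, 25.0], index=genes)
        hl_mut = pd.Series([12.0, 18.0, np.inf], index=genes[:3])
        res = basal_comparison(t0, t0, 1.0, 1.0, hl_wt, hl_mut, gene_ids=genes)
        assert list(res.table.index) == ["g0", "g1"]
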