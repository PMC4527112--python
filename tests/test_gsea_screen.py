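import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from psoriomics.gsea_screen import (
    OrderedGeneList,
    build_ordered_list,
    disease_specificity_fractions,
    moderated_t_fit,
    rank_degps_by_specificity,
    screen_gene_sets,
    stratified_gsea,
)
from psoriomics.synthetic import simulate_disease_panel


def _expr(rng, n_genes, n_per_group):
    data = rng.normal(0, 1, size=(n_genes, 2 * n_per_group))
    idx = [f"g{i}" for i in range(n_genes)]
    cols = [f"s{i}" for i in range(2 * n_per_group)]
    groups = ["ctl"] * n_per_group + ["trt"] * n_per_group
    return pd.DataFrame(data, index=idx, columns=cols), groups


class TestBuildOrderedList:
    def test_strong_effect_ranks_first(self, rng):
        expr, groups = _expr(rng, 100, 4)
        expr.loc["g5", ["s4", "s5", "s6", "s7"]] += 10.0
        olist = build_ordered_list(expr, groups)
        assert olist.gene_ids[0] == "g5"

    def test_zero_prior_df_recovers_ordinary_t(self, rng):
        expr, groups = _expr(rng, 50, 5)
        fit = moderated_t_fit(expr, groups, prior_df=0)
        t_ref = sps.ttest_ind(
            expr.iloc[:, 5:], expr.iloc[:, :5], axis=1, equal_var=True
        )
        assert np.allclose(fit["t"], t_ref.statistic, atol=1e-10)
        assert np.allclose(fit["p"], t_ref.pvalue, atol=1e-10)

    def test_all_null_calibration(self, rng):
        hits, total = 0, 0
        for _ in range(50):
            expr, groups = _expr(rng, 400, 4)
            fit = moderated_t_fit(expr, groups)
            hits += (fit["p"] < 0.05).sum()
            total += len(fit)
        assert 0.03 <= hits / total <= 0.07

    def test_small_group_rejected(self, rng):
        expr, _ = _expr(rng, 10, 2)
        with pytest.raises(ValueError):
            build_ordered_list(expr, ["a", "a", "a", "b"])

    def test_ranking_is_descending(self, rng):
        expr, groups = _expr(rng, 80, 4)
        olist = build_ordered_list(expr, groups)
        assert (np.diff(olist.table["signed_score"]) <= 0).all()


class TestScreenGeneSets:
    def _panel(self, rng, n_lists=10, n_genes=500, planted=None):
        panel = {}
        for i in range(n_lists):
            score = -np.log10(rng.uniform(size=n_genes)) * rng.choice([-1, 1], n_genes)
            table = pd.DataFrame({"gene_id": [f"g{j}" for j in range(n_genes)],
                                  "signed_score": score})
            if planted is not None and i == planted:
                table.loc[table["gene_id"].isin(self.up), "signed_score"] = (
                    8.0 + rng.normal(0, 0.5, len(self.up))
                )
                table.loc[table["gene_id"].isin(self.down), "signed_score"] = (
                    -8.0 + rng.normal(0, 0.5, len(self.down))
                )
            panel[f"list{i:02d}"] = OrderedGeneList(table)
        return panel

    def setup_method(self, method):
        self.up = [f"g{j}" for j in range(0, 60, 2)]
        self.down = [f"g{j}" for j in range(1, 61, 2)]

    def test_extreme_separation_maximizes_combined(self, rng):
        n = 200
        genes = [f"g{j}" for j in range(n)]
        score = np.linspace(10, -10, n)
        table = pd.DataFrame({"gene_id": genes, "signed_score": score})
        panel = {"perfect": OrderedGeneList(table)}
        up, down = genes[:20], genes[-20:]
        out = screen_gene_sets(panel, up, down)
        z_up, z_down = out.loc[0, "z_up"], out.loc[0, "z_down"]
        assert z_up > 7 and z_down < -7

    def test_null_lists_center_on_zero(self, rng):
        panel = self._panel(rng, n_lists=30)
        out = screen_gene_sets(panel, self.up, self.down)
        assert abs(out["combined"].mean()) < 0.6

    def test_spiked_list_ranks_first_with_low_fdr(self, rng):
        panel = self._panel(rng, n_lists=20, planted=13)
        out = screen_gene_sets(panel, self.up, self.down)
        assert out.loc[0, "list_id"] == "list13"
        assert out.loc[0, "fdr"] < 0.05

    def test_monotone_transform_invariance(self, rng):
        panel = self._panel(rng, n_lists=3)
        out1 = screen_gene_sets(panel, self.up, self.down)
        warped = {
            name: OrderedGeneList(
                ol.table.assign(signed_score=np.sinh(ol.table["signed_score"] / 4))
            )
            for name, ol in panel.items()
        }
        out2 = screen_gene_sets(warped, self.up, self.down)
        m = out1.set_index("list_id")["combined"]
        w = out2.set_index("list_id")["combined"]
        assert np.allclose(m, w.reindex(m.index), atol=1e-9)

    def test_empty_set_flagged_not_scored(self, rng):
        panel = self._panel(rng, n_lists=2)
        out = screen_gene_sets(panel, ["absent_gene"], self.down)
        assert not out["scored"].any()


class TestDiseaseSpecificityFractions:
    def _panel_with(self, entries):
        """entries: list of dicts gene -> (signed_score, assayed)"""
        panel = {}
        for i, e in enumerate(entries):
            genes = sorted(e)
            table = pd.DataFrame({
                "gene_id": genes,
                "signed_score": [e[g][0] for g in genes],
                "assayed": [e[g][1] for g in genes],
            })
            panel[f"d{i}"] = OrderedGeneList(table)
        return panel

    def test_fraction_counts_concordant_significant(self):
        hit, miss = 5.0, 0.2  # -log10 p: significant vs not
        panel = self._panel_with([
            {"g": (hit, True)}, {"g": (hit, True)},
            {"g": (miss, True)}, {"g": (-hit, True)},
        ])
        degps = pd.DataFrame({"gene_id": ["g"], "direction": ["increased"]})
        prof = disease_specificity_fractions(degps, panel)
        assert prof.loc[0, "numerator"] == 2
        assert prof.loc[0, "denominator"] == 4
        assert prof.loc[0, "fraction"] == pytest.approx(0.5)

    def test_unassayed_platform_shrinks_denominator(self):
        panel = self._panel_with([
            {"g": (5.0, True)}, {"g": (5.0, True)},
            {"g": (5.0, True)}, {"g": (5.0, False)},
        ])
        degps = pd.DataFrame({"gene_id": ["g"], "direction": ["increased"]})
        prof = disease_specificity_fractions(degps, panel)
        assert prof.loc[0, "denominator"] == 3

    def test_nowhere_concordant_is_fully_specific(self):
        panel = self._panel_with([{"g": (-5.0, True)}, {"g": (0.5, True)}])
        degps = pd.DataFrame({"gene_id": ["g"], "direction": ["increased"]})
        prof = disease_specificity_fractions(degps, panel)
        assert prof.loc[0, "fraction"] == 0.0

    def test_fractions_non_increasing_in_alpha(self, rng):
        degps = pd.DataFrame({
            "gene_id": [f"G{i + 1:05d}" for i in range(30)],
            "direction": "increased",
        })
        ps = simulate_disease_panel(10, 200, degps["gene_id"], seed=4)
        loose = disease_specificity_fractions(degps, ps.panel, alpha=0.05)
        strict = disease_specificity_fractions(degps, ps.panel, alpha=0.01)
        assert (strict["numerator"] <= loose["numerator"]).all()


class TestStratifiedGsea:
    def test_window_count(self, rng):
        genes = [f"g{i}" for i in range(200)]
        score = rng.normal(size=200)
        target = OrderedGeneList(pd.DataFrame({"gene_id": genes, "signed_score": score}))
        res = stratified_gsea(genes[:153], target, window_size=10)
        assert len(res.window_statistics) == 144

    def test_planted_gradient_detected(self):
        degps = [f"G{i + 1:05d}" for i in range(153)]
        ps = simulate_disease_panel(
            12, 3000, degps, seed=9, specificity_gradient=8.0
        )
        degp_df = pd.DataFrame({"gene_id": degps, "direction": "increased"})
        prof = disease_specificity_fractions(degp_df, ps.panel)
        ordered = rank_degps_by_specificity(prof)
        res = stratified_gsea(ordered, ps.induction_list, seed=1)
        assert res.trend_slope < 0
        assert res.trend_p < 0.05

    def test_reversed_ordering_negates_slope(self, rng):
        genes = [f"g{i}" for i in range(400)]
        score = rng.normal(size=400)
        # build a linear induction gradient over the first 60 genes
        score[:60] = np.linspace(6, -2, 60) + rng.normal(0, 0.3, 60)
        target = OrderedGeneList(pd.DataFrame({"gene_id": genes, "signed_score": score}))
        fwd = stratified_gsea(genes[:60], target, seed=0)
        rev = stratified_gsea(genes[:60][::-1], target, seed=0)
        assert fwd.trend_slope < 0 < rev.trend_slope
        assert fwd.trend_slope == pytest.approx(-rev.trend_slope, rel=0.3)

    def test_too_few_degps_rejected(self, rng):
        genes = [f"g{i}" for i in range(50)]
        target = OrderedGeneList(
            pd.DataFrame({"gene_id": genes, "signed_score": rng.normal(size=50)})
        )
        with pytest.raises(ValueError):
            stratified_gsea(genes[:5], target, window_size=10)

    def test_specificity_ordering_deterministic_under_ties(self):
        prof = pd.DataFrame({
            "gene_id": ["b", "a", "c"],
            "direction": "increased",
            "numerator": [1, 1, 0],
            "denominator": [2, 2, 2],
            "fraction": [0.5, 0.5, 0.0],
            "undefined": False,
        })
        fc = pd.Series([2.0, 1.5, 3.0], index=["a", "b", "c"])
        assert rank_degps_by_specificity(prof, fc) == ["c", "a", "b"]
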