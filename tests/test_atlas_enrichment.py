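import numpy as np
import pandas as pd
import pytest

from psoriomics.atlas_enrichment import (
    AtlasMatrix,
    SignatureSet,
    compartment_signed_p,
    cumulative_overlap_curve,
    sampling_null_test,
    specificity_ratio_correlation,
    top_signature_proteins,
)
from psoriomics.synthetic import simulate_atlas


def _atlas(data, contexts, reps=3):
    cols = {}
    k = 0
    for ctx in contexts:
        for r in range(reps):
            cols[f"{ctx}__rep{r + 1}"] = data[:, k]
            k += 1
    return AtlasMatrix(pd.DataFrame(cols, index=[f"p{i}" for i in range(data.shape[0])]))


class TestCompartmentSignedP:
    def test_separated_protein_scores_high(self, rng):
        data = rng.lognormal(1, 0.1, size=(10, 9))
        data[0, 0:3] = 50.0
        data[0, 3:] = 0.01
        atlas = _atlas(data, ["a", "b", "c"])
        scores = compartment_signed_p(atlas, "a")
        assert scores["p0"] > 2.0  # p << 0.01 in favour of the context
        assert scores.attrs["method"] == "regression"

    def test_constant_protein_scores_near_zero(self):
        data = np.full((3, 9), 5.0)
        atlas = _atlas(data, ["a", "b", "c"])
        scores = compartment_signed_p(atlas, "a")
        assert abs(scores["p0"]) < 0.1

    def test_null_type_i_error(self, rng):
        data = rng.lognormal(1, 0.3, size=(2000, 9))
        atlas = _atlas(data, ["a", "b", "c"])
        scores = compartment_signed_p(atlas, "a")
        frac = np.mean(np.abs(scores) > -np.log10(0.05))
        assert 0.03 <= frac <= 0.07

    def test_single_column_context_uses_rank_fallback(self, rng):
        df = pd.DataFrame(
            rng.lognormal(1, 0.3, size=(20, 3)),
            index=[f"p{i}" for i in range(20)],
            columns=["a", "b", "c"],
        )
        scores = compartment_signed_p(AtlasMatrix(df), "a")
        assert scores.attrs["method"] == "rank"

    def test_missing_context_rejected(self, rng):
        data = rng.lognormal(1, 0.3, size=(5, 6))
        atlas = _atlas(data, ["a", "b"])
        with pytest.raises(ValueError):
            compartment_signed_p(atlas, "zz")


class TestTopSignatureProteins:
    def test_positive_scores_rank_first(self):
        scores = pd.Series(
            np.r_[np.linspace(5, 1, 12), np.linspace(-1, -8, 8)],
            index=[f"p{i:02d}" for i in range(20)],
        )
        sig = top_signature_proteins(scores, k=12)
        assert set(sig.protein_ids) == {f"p{i:02d}" for i in range(12)}

    def test_k_one_is_argmax(self):
        scores = pd.Series([1.0, 9.0, 3.0], index=["a", "b", "c"])
        assert top_signature_proteins(scores, k=1).protein_ids == ["b"]

    def test_ties_break_lexically_and_deterministically(self):
        scores = pd.Series([2.0, 2.0, 2.0, 1.0], index=["z", "m", "a", "b"])
        sig1 = top_signature_proteins(scores, k=2)
        sig2 = top_signature_proteins(scores, k=2)
        assert sig1.protein_ids == ["a", "m"] == sig2.protein_ids

    def test_short_input_warns_and_returns_all(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.warns(UserWarning):
            sig = top_signature_proteins(scores, k=12)
        assert len(sig.protein_ids) == 2

    def test_recovers_planted_atlas_signature(self):
        atlas, truth = simulate_atlas(300, ["bm", "pd", "rd"], 12, effect=10.0, seed=5)
        scores = compartment_signed_p(atlas, "pd")
        sig = top_signature_proteins(scores, context="pd", k=12)
        planted = set(truth.loc[truth["planted_context"] == "pd", "protein_id"])
        assert len(set(sig.protein_ids) & planted) >= 11

    def test_unit_effect_atlas_scores_stay_small(self):
        atlas, _ = simulate_atlas(200, 3, 12, effect=1.0, seed=8)
        scores = compartment_signed_p(atlas, "ctx1")
        assert np.mean(np.abs(scores) > 2) < 0.05


class TestSamplingNullTest:
    def _fixture(self, rng, n=2000, k=12, boost=None):
        fc = pd.Series(2.0 ** rng.normal(0, 0.5, n),
                       index=[f"p{i}" for i in range(n)])
        sig_ids = [f"p{i}" for i in range(k)]
        if boost is not None:
            fc.loc[sig_ids] = 2.0 ** (boost + rng.normal(0, 0.1, k))
        return fc, SignatureSet("x", sig_ids, fc.loc[sig_ids])

    def test_whole_universe_signature_gives_p_one(self, rng):
        fc, _ = self._fixture(rng, n=30, k=12)
        sig = SignatureSet("x", fc.index.tolist(), fc)
        assert sampling_null_test(fc, sig, n_trials=100, seed=0).p_value == 1.0

    def test_planted_elevated_signature_detected(self, rng):
        fc, sig = self._fixture(rng, boost=2.0)
        res = sampling_null_test(fc, sig, n_trials=10_000, seed=1)
        assert res.p_value < 0.01
        assert res.null_summary["n_trials"] == 10_000

    def test_seed_reproducibility(self, rng):
        fc, sig = self._fixture(rng, boost=1.0)
        a = sampling_null_test(fc, sig, n_trials=2000, seed=7)
        b = sampling_null_test(fc, sig, n_trials=2000, seed=7)
        assert a.p_value == b.p_value and a.null_summary == b.null_summary

    def test_scale_invariance_of_p(self, rng):
        fc, sig = self._fixture(rng, boost=1.0)
        a = sampling_null_test(fc, sig, n_trials=2000, seed=3)
        b = sampling_null_test(fc * 16.0, sig, n_trials=2000, seed=3)
        assert a.p_value == pytest.approx(b.p_value)

    def test_signature_outside_universe_rejected(self, rng):
        fc, _ = self._fixture(rng, n=10, k=5)
        sig = SignatureSet("x", [f"p{i}" for i in range(10)] + ["extra"], None)
        with pytest.raises(ValueError, match="extra"):
            sampling_null_test(fc, sig, n_trials=10, seed=0)


class TestSpecificityRatioCorrelation:
    def test_monotone_construction_gives_unity(self, rng):
        data = rng.lognormal(2, 0.5, size=(50, 9))
        atlas = _atlas(data, ["b_cell", "t_cell", "nk"])
        ratio = (atlas.abundance[[c for c in atlas.abundance.columns if c.startswith("b_cell")]]
                 .mean(axis=1) + 0.5) / (
            atlas.abundance[[c for c in atlas.abundance.columns if not c.startswith("b_cell")]]
            .mean(axis=1) + 0.5)
        fc = pd.Series(2.0 ** np.log2(ratio), index=atlas.protein_ids)
        res = specificity_ratio_correlation(atlas, "b_cell", fc)
        assert res.statistic == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        data = rng.lognormal(2, 0.5, size=(1764, 9))
        atlas = _atlas(data, ["b_cell", "t_cell", "nk"])
        fc = pd.Series(2.0 ** rng.normal(0, 0.5, 1764), index=atlas.protein_ids)
        res = specificity_ratio_correlation(atlas, "b_cell", fc)
        assert abs(res.statistic) < 0.06

    def test_no_overlap_rejected(self, rng):
        data = rng.lognormal(2, 0.5, size=(5, 6))
        atlas = _atlas(data, ["a", "b"])
        fc = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(ValueError):
            specificity_ratio_correlation(atlas, "a", fc)


class TestCumulativeOverlapCurve:
    def _brute_force_area(self, ranked, members):
        """Independent enumeration of the curve and area at tiny N."""
        n = len(ranked)
        k = len(members)
        area = 0.0
        c = 0
        for i, g in enumerate(ranked, start=1):
            if g in members:
                c += 1
            area += (c - i * k / n) / n
        return area

    def test_hand_enumeration_at_small_n(self):
        ranked = [f"g{i}" for i in range(10)]
        members = {"g0", "g1", "g2"}
        curve, res = cumulative_overlap_curve(ranked, members, n_perm=200, seed=0)
        assert res.statistic == pytest.approx(self._brute_force_area(ranked, members))
        # all members on top achieves the analytic maximum k(N-k)/(2N)
        assert res.statistic == pytest.approx(3 * 7 / 20)

    def test_curve_ends_at_signature_size(self, rng):
        ranked = [f"g{i}" for i in range(50)]
        members = set(rng.choice(ranked, size=8, replace=False))
        curve, _ = cumulative_overlap_curve(ranked, members, n_perm=100, seed=0)
        assert curve[-1] == len(members)

    def test_random_placement_has_zero_mean_area(self, rng):
        areas = []
        ranked = [f"g{i}" for i in range(200)]
        for _ in range(200):
            members = set(rng.choice(ranked, size=10, replace=False))
            areas.append(self._brute_force_area(ranked, members))
        assert abs(np.mean(areas)) < 0.5

    def test_antisymmetric_under_list_reversal(self, rng):
        ranked = [f"g{i}" for i in range(60)]
        members = set(rng.choice(ranked, size=6, replace=False))
        _, fwd = cumulative_overlap_curve(ranked, members, n_perm=50, seed=0)
        _, rev = cumulative_overlap_curve(ranked[::-1], members, n_perm=50, seed=0)
        assert fwd.statistic == pytest.approx(-rev.statistic, abs=len(members) / 60)

    def test_permutation_and_wilcoxon_agree_in_magnitude(self, rng):
        ranked = [f"g{i}" for i in range(600)]
        members = set(ranked[:12])  # strongly top-enriched
        _, res = cumulative_overlap_curve(ranked, members, n_perm=5000, seed=2)
        assert res.p_value < 0.01 and res.extras["wilcoxon_p"] < 0.01

    def test_missing_members_rejected(self):
        with pytest.raises(ValueError):
            cumulative_overlap_curve(["a", "b"], ["zz"], n_perm=10, seed=0)
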