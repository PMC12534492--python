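"""Omics integration: matching, left-shifted imputation, z-scoring,
cross-omics correlations, reproducibility, cluster ordering."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from phosphonorm import (
    GeneProteinMap,
    ImputationParams,
    SampleDesign,
    compare_condition_correlations,
    crossomics_replicate_correlations,
    impute_gaussian,
    match_features,
    replicate_reproducibility_and_cv,
    sample_correlation_clustermap,
    zscore_features,
)
from phosphonorm.integration import MatchedOmics
from phosphonorm.io import log2_transform


class TestMatchFeatures:
    def test_disjoint_id_sets_rejected(self):
        prot = make_matrix(np.ones((3, 2)), scale="log2", prefix="P")
        trans = make_matrix(np.ones((3, 2)), scale="log2", prefix="G")
        gpmap = GeneProteinMap(pd.DataFrame(
            {"gene_id": ["X1"], "protein_group": ["Y1"]}))
        with pytest.raises(ValueError, match="no overlapping"):
            match_features(prot, trans, gpmap)

    def test_identity_map_keeps_all_features(self):
        prot = make_matrix(np.random.default_rng(0).normal(size=(100, 2)),
                           scale="log2", prefix="P")
        trans = make_matrix(np.random.default_rng(1).normal(size=(100, 2)),
                            scale="log2", prefix="G")
        gpmap = GeneProteinMap(pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(100)],
            "protein_group": [f"P{i}" for i in range(100)]}))
        matched = match_features(prot, trans, gpmap)
        assert len(matched.pairs) == 100
        assert list(matched.proteome.feature_ids) == matched.pairs["protein_group"].tolist()

    def test_ambiguous_mappings_excluded(self):
        prot = make_matrix(np.ones((3, 2)), scale="log2", prefix="P")
        trans = make_matrix(np.ones((3, 2)), scale="log2", prefix="G")
        gpmap = GeneProteinMap(pd.DataFrame({
            "gene_id": ["G0", "G0", "G1"],
            "protein_group": ["P0", "P1", "P2"]}))
        matched = match_features(prot, trans, gpmap)
        assert matched.pairs["gene_id"].tolist() == ["G1"]

    def test_simulated_pair_fully_matched(self, omics_pair, small_config):
        proteome, transcriptome, gpmap, _ = omics_pair
        matched = match_features(log2_transform(proteome),
                                 log2_transform(transcriptome), gpmap)
        assert len(matched.pairs) == small_config.n_proteins


class TestImputeGaussian:
    def test_complete_matrix_unchanged(self):
        mat = make_matrix(np.random.default_rng(2).normal(20, 1, (10, 6)))
        out = impute_gaussian(mat, ImputationParams(seed=0))
        pd.testing.assert_frame_equal(out.data, mat.data)

    def test_draws_match_downshifted_distribution(self):
        """1e5 imputed draws for a feature with mean 20, sd 1 recover
        N(20 - 3, 0.3) within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        obs = rng.normal(20.0, 1.0, 1000)
        obs = 20.0 + (obs - obs.mean()) / obs.std(ddof=1)  # exact mean/sd
        row = np.concatenate([obs, np.full(100_000, np.nan)])
        mat = make_matrix(row[None, :])
        out = impute_gaussian(mat, ImputationParams(seed=4))
        imputed = out.data.to_numpy()[0, 1000:]
        assert imputed.mean() == pytest.approx(17.0, abs=0.01)
        assert imputed.std(ddof=1) == pytest.approx(0.3, abs=0.01)

    def test_only_missing_cells_touched(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(20, 1, (50, 8))
        mask = rng.uniform(size=vals.shape) < 0.2
        vals_missing = np.where(mask, np.nan, vals)
        mat = make_matrix(vals_missing)
        out = impute_gaussian(mat, ImputationParams(seed=6))
        observed_before = vals_missing[~mask]
        observed_after = out.data.to_numpy()[~mask]
        np.testing.assert_array_equal(observed_before, observed_after)
        assert np.isfinite(out.data.to_numpy()).all()

    def test_zero_sd_feature_imputes_at_mean(self):
        mat = make_matrix([[5.0, 5.0, 5.0, np.nan]])
        out = impute_gaussian(mat, ImputationParams(seed=7))
        assert out.data.iloc[0, 3] == 5.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        vals = np.where(rng.uniform(size=(30, 6)) < 0.3, np.nan,
                        rng.normal(20, 1, (30, 6)))
        mat = make_matrix(vals)
        a = impute_gaussian(mat, ImputationParams(seed=9))
        b = impute_gaussian(mat, ImputationParams(seed=9))
        pd.testing.assert_frame_equal(a.data, b.data)


class TestZscore:
    def test_row_mean_zero_sd_one(self):
        out = zscore_features(make_matrix([[1.0, 2.0, 3.0]]))
        assert out.data.iloc[0].mean() == pytest.approx(0.0, abs=1e-10)
        assert out.data.iloc[0].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_idempotent(self):
        mat = make_matrix(np.random.default_rng(10).normal(size=(20, 6)))
        once = zscore_features(mat)
        twice = zscore_features(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_constant_row_rejected_by_name(self):
        with pytest.raises(ValueError, match="F1"):
            zscore_features(make_matrix([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]))


def _single_group_design(n_samples):
    rows = [{"sample_id": f"S{j}", "cell_type": "beta", "treatment": "control",
             "replicate": j + 1} for j in range(n_samples)]
    return SampleDesign(pd.DataFrame(rows))


class TestCrossOmics:
    def test_identical_replicates_give_perfect_fit(self):
        vals = np.random.default_rng(11).normal(20, 2, (100, 1))
        prot = make_matrix(vals, prefix="P")
        trans = make_matrix(vals, prefix="G")
        prot.data.columns = trans.data.columns = ["S0"]
        matched = MatchedOmics(prot, trans, pd.DataFrame())
        res = crossomics_replicate_correlations(matched, _single_group_design(1))
        row = res.iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(1.0)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_affine_transform_keeps_r_one(self):
        vals = np.random.default_rng(12).normal(20, 2, (100, 1))
        prot = make_matrix(vals, prefix="P")
        trans = make_matrix(2 * vals + 1, prefix="G")
        prot.data.columns = trans.data.columns = ["S0"]
        matched = MatchedOmics(prot, trans, pd.DataFrame())
        res = crossomics_replicate_correlations(matched, _single_group_design(1))
        assert res.iloc[0]["r_squared"] == pytest.approx(1.0)
        assert res.iloc[0]["slope"] == pytest.approx(2.0)

    def test_independent_features_give_near_zero_r(self):
        n = 4481
        rng = np.random.default_rng(13)
        prot = make_matrix(rng.normal(20, 2, (n, 1)), prefix="P")
        trans = make_matrix(rng.normal(10, 2, (n, 1)), prefix="G")
        prot.data.columns = trans.data.columns = ["S0"]
        matched = MatchedOmics(prot, trans, pd.DataFrame())
        res = crossomics_replicate_correlations(matched, _single_group_design(1))
        assert abs(res.iloc[0]["pearson_r"]) < 3 / np.sqrt(n)

    def test_all_replicate_pairings_produced(self, omics_pair):
        proteome, transcriptome, gpmap, truth = omics_pair
        matched = match_features(log2_transform(proteome),
                                 log2_transform(transcriptome), gpmap)
        res = crossomics_replicate_correlations(matched, truth.design)
        # 3 cell types x 2 treatments x (3 proteome x 3 transcriptome reps)
        assert len(res) == 6 * 9
        assert np.allclose(res["r_squared"], res["pearson_r"] ** 2, atol=1e-12)


class TestCompareConditions:
    def _results(self, rs_x, rs_y):
        rows = [{"cell_type": "alpha", "treatment": "control", "pearson_r": r}
                for r in rs_x]
        rows += [{"cell_type": "alpha", "treatment": "IFNg", "pearson_r": r}
                 for r in rs_y]
        return pd.DataFrame(rows)

    def test_identical_sets_give_p_one(self):
        res = self._results([0.8, 0.8, 0.8], [0.8, 0.8, 0.8])
        out = compare_condition_correlations(
            res, ("alpha", "control"), ("alpha", "IFNg"))
        assert out["p"] == 1.0

    def test_separated_sets_detected(self):
        res = self._results([0.90, 0.91, 0.89], [0.50, 0.51, 0.49])
        out = compare_condition_correlations(
            res, ("alpha", "control"), ("alpha", "IFNg"))
        assert out["p"] < 0.05

    def test_textbook_t_statistic(self):
        x, y = [0.9, 0.8, 0.7], [0.6, 0.5, 0.4]
        res = self._results(x, y)
        out = compare_condition_correlations(
            res, ("alpha", "control"), ("alpha", "IFNg"))
        from scipy import stats
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=True)
        assert out["t"] == pytest.approx(t_ref)
        assert out["p"] == pytest.approx(p_ref)

    def test_degenerate_group_rejected(self):
        res = self._results([0.9], [0.5, 0.6])
        with pytest.raises(ValueError):
            compare_condition_correlations(
                res, ("alpha", "control"), ("alpha", "IFNg"))


class TestReproducibilityAndCV:
    def test_duplicated_replicates_have_unit_r2_and_zero_cv(self):
        col = np.random.default_rng(14).normal(20, 2, 50)
        mat = make_matrix(np.column_stack([col, col, col]))
        design = _single_group_design(3)
        mat.data.columns = design.sample_ids
        out = replicate_reproducibility_and_cv(mat, design)
        assert np.allclose(out["pairwise"]["r_squared"], 1.0)
        assert np.allclose(out["cv_per_feature"].to_numpy(), 0.0)

    def test_recovers_generator_cv_target(self, omics_pair, small_config):
        proteome = omics_pair[0]
        truth = omics_pair[3]
        out = replicate_reproducibility_and_cv(proteome, truth.design)
        target = small_config.target_cv_proteomics
        assert abs(out["mean_cv"] - target) / target < 0.10

    def test_single_replicate_cv_missing(self):
        mat = make_matrix(np.random.default_rng(15).normal(20, 1, (10, 1)))
        design = _single_group_design(1)
        mat.data.columns = design.sample_ids
        out = replicate_reproducibility_and_cv(mat, design)
        assert out["cv_per_feature"].isna().all().all()
        assert out["pairwise"].empty


class TestClustermap:
    def test_identical_samples_correlate_and_sit_adjacent(self):
        rng = np.random.default_rng(16)
        base = rng.normal(0, 1, 40)
        other = rng.normal(0, 1, (40, 2))
        mat = make_matrix(np.column_stack([base, other[:, 0], base, other[:, 1]]))
        corr, order, _ = sample_correlation_clustermap(zscore_features(mat))
        assert corr.loc["S0", "S2"] == pytest.approx(1.0)
        assert abs(order.index("S0") - order.index("S2")) == 1

    def test_matrix_symmetric_with_unit_diagonal(self, omics_pair):
        proteome = omics_pair[0]
        mat = impute_gaussian(log2_transform(proteome), ImputationParams(seed=17))
        z = zscore_features(mat)
        corr, order, _ = sample_correlation_clustermap(z)
        arr = corr.to_numpy()
        assert np.allclose(arr, arr.T, atol=1e-12)
        assert (np.diag(arr) == 1.0).all()
        assert sorted(order) == sorted(proteome.sample_ids)

    def test_cell_types_form_contiguous_blocks(self, omics_pair):
        """Strong marker structure: single-linkage ordering groups each cell
        type's samples contiguously."""
        proteome, _, _, truth = omics_pair
        mat = impute_gaussian(log2_transform(proteome), ImputationParams(seed=18))
        z = zscore_features(mat)
        _, order, _ = sample_correlation_clustermap(z)
        ct_of = dict(zip(truth.design.table["sample_id"], truth.design.table["cell_type"]))
        seq = [ct_of[s] for s in order]
        n_blocks = 1 + sum(a != b for a, b in zip(seq, seq[1:]))
        assert n_blocks == len(set(seq))
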