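"""Multivariate statistics: FDR, principal variables, PCA-MV, imputation,
cloud geometry, group tests, regression partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ephyscensus import (agnes_coefficient, cloud_median_distance,
                         explained_variance_single, explained_variance_subset,
                         fdr_adjust, group_compare, impute, local_pca_variance,
                         ordination_quality, pairwise_correlations, project,
                         promax_rotate, rank_renormalize, sequential_regression,
                         synth_feature_matrix, variance_ratio_test, vbpca_fit)
from ephyscensus.simulate import apply_missingness
from ephyscensus.stats import compare_cloud_sizes, standardize


def bh_oracle(pvals, alpha):
    """Textbook step-up rule, written independently of the implementation."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            k_max = rank
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_max]] = True
    return mask


class TestCorrelations:
    def test_33_variables_enumerate_528_pairs(self, rng):
        m = pd.DataFrame(rng.standard_normal((20, 33)))
        assert len(pairwise_correlations(m)) == 528

    def test_exact_linear_pair(self, rng):
        x = rng.standard_normal(50)
        m = pd.DataFrame({"x": x, "y": 2 * x, "z": rng.standard_normal(50)})
        tab = pairwise_correlations(m).set_index(["var_a", "var_b"])
        assert tab.loc[("x", "y"), "r"] == pytest.approx(1.0)
        assert tab.loc[("x", "y"), "p"] < 1e-20

    def test_null_columns_mostly_uncorrelated(self, rng):
        m = pd.DataFrame(rng.standard_normal((100, 10)))
        tab = pairwise_correlations(m)
        assert (np.abs(tab["r"]) < 0.3).mean() >= 0.95

    def test_pairwise_complete_n_tracks_missingness(self, rng):
        m = pd.DataFrame(rng.standard_normal((40, 4)))
        m.iloc[:10, 0] = np.nan
        tab = pairwise_correlations(m).set_index(["var_a", "var_b"])
        assert tab.loc[(0, 1), "n"] == 30
        assert tab.loc[(2, 3), "n"] == 40

    def test_constant_variable_marked_missing(self, rng):
        m = pd.DataFrame({"a": np.ones(20), "b": rng.standard_normal(20)})
        tab = pairwise_correlations(m)
        assert np.isnan(tab["r"].iloc[0])


class TestFDR:
    def test_hand_worked_case(self):
        mask, thresh = fdr_adjust([0.01, 0.04, 0.03, 0.005], alpha=0.05)
        assert mask.all()
        assert thresh == 0.04

    def test_uniform_small_p_all_pass(self):
        mask, _ = fdr_adjust(np.full(528, 0.01), alpha=0.05)
        assert mask.all()

    def test_all_ones_none_pass(self):
        mask, thresh = fdr_adjust(np.ones(100))
        assert not mask.any()
        assert np.isnan(thresh)

    def test_empty_input(self):
        mask, thresh = fdr_adjust([])
        assert mask.size == 0

    def test_matches_step_up_oracle_exhaustively(self, rng):
        for _ in range(200):
            m = rng.integers(1, 7)
            p = np.round(rng.random(m), 3)
            mask, _ = fdr_adjust(p, alpha=0.05)
            np.testing.assert_array_equal(mask, bh_oracle(p, 0.05))


class TestPrincipalVariables:
    def test_uncorrelated_variable_hits_noise_floor(self):
        c = pd.DataFrame(np.eye(33))
        shares = explained_variance_single(c)
        np.testing.assert_allclose(shares, 1.0 / 33.0)

    def test_two_perfectly_correlated_variables(self):
        c = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(explained_variance_single(c), 1.0)

    def test_null_data_shares_near_floor(self, rng):
        m = pd.DataFrame(rng.standard_normal((200, 10)))
        shares = explained_variance_single(m.corr())
        assert ((shares > 0.10) & (shares < 0.25)).all()

    def test_subset_of_everything_explains_all(self, rng):
        m = pd.DataFrame(rng.standard_normal((50, 5)),
                         columns=list("abcde"))
        assert explained_variance_subset(m, list("abcde")) == pytest.approx(1.0)

    def test_factor_proxies_explain_most_variance(self, rng):
        f = rng.standard_normal((120, 2))
        load = rng.normal(0, 1, size=(10, 2))
        x = f @ load.T + 0.2 * rng.standard_normal((120, 10))
        m = pd.DataFrame(np.column_stack([x, f]),
                         columns=[f"v{k}" for k in range(10)] + ["f1", "f2"])
        assert explained_variance_subset(m, ["f1", "f2"]) >= 0.80


class TestPCAMissingValues:
    def test_complete_data_matches_standard_pca(self, rng):
        from sklearn.decomposition import PCA
        m = synth_feature_matrix(100, 33, n_factors=3, seed=4)
        model = vbpca_fit(m, 2)
        z, _, _ = standardize(m)
        sk = PCA(2, svd_solver="full").fit(z.to_numpy())
        scores = sk.transform(z.to_numpy())
        for k in range(2):
            r, _ = sps.pearsonr(model.scores.iloc[:, k], scores[:, k])
            assert abs(r) > 0.99
        np.testing.assert_allclose(model.explained,
                                   sk.explained_variance_ratio_, atol=0.01)

    def test_rank_one_direction_survives_masking(self, rng):
        w = rng.normal(size=12)
        x = np.outer(rng.standard_normal(80), w) + 0.2 * rng.standard_normal((80, 12))
        m = apply_missingness(pd.DataFrame(x), 0.20, seed=1)
        model = vbpca_fit(m, 2)
        sd = m.std(ddof=1).to_numpy()
        w_std = w / sd
        lead = model.loadings.to_numpy()[:, 0]
        cosine = abs(w_std @ lead) / (np.linalg.norm(w_std) * np.linalg.norm(lead))
        assert cosine > 0.95

    def test_isotropic_noise_shares_near_uniform(self, rng):
        m = pd.DataFrame(rng.standard_normal((200, 10)))
        model = vbpca_fit(m, 2)
        np.testing.assert_allclose(model.explained, 0.1, atol=0.05)

    def test_too_much_missingness_rejected(self, rng):
        m = pd.DataFrame(rng.standard_normal((10, 4)))
        m.iloc[:8, :3] = np.nan
        with pytest.raises(ValueError):
            vbpca_fit(m, 2)


class TestPromaxAndProjection:
    @pytest.fixture(scope="class")
    def block_model(self):
        rng = np.random.default_rng(11)
        f = rng.standard_normal((150, 2))
        load = np.zeros((12, 2))
        load[:6, 0] = 1.0
        load[6:, 1] = 1.0
        x = f @ load.T + 0.1 * rng.standard_normal((150, 12))
        m = pd.DataFrame(x, columns=[f"v{k}" for k in range(12)])
        return m, vbpca_fit(m, 2)

    def test_reconstruction_invariant_under_rotation(self, block_model):
        _, model = block_model
        rotated = promax_rotate(model)
        before = model.scores.to_numpy() @ model.loadings.to_numpy().T
        after = rotated.scores.to_numpy() @ rotated.loadings.to_numpy().T
        assert np.abs(before - after).max() < 1e-8

    def test_two_block_structure_gets_simple_loadings(self, block_model):
        _, model = block_model
        lam = np.abs(promax_rotate(model).loadings.to_numpy())
        lam = lam / np.abs(lam).max(axis=0, keepdims=True)
        primary = lam.max(axis=1)
        secondary = lam.min(axis=1)
        assert (primary > 0.8 * primary.max()).all() or (secondary < 0.3).all()

    def test_self_projection_reproduces_scores(self, block_model):
        m, model = block_model
        rotated = promax_rotate(model)
        proj = project(rotated, m)
        np.testing.assert_allclose(proj.to_numpy(), rotated.scores.to_numpy(),
                                   atol=1e-6)

    def test_mean_cell_scores_zero(self, block_model):
        m, model = block_model
        mean_cell = pd.DataFrame([m.mean()], index=["avg"])
        np.testing.assert_allclose(project(model, mean_cell).to_numpy(), 0.0,
                                   atol=0.05)

    def test_masked_cell_score_recovered(self, block_model):
        m, model = block_model
        cell = m.iloc[[0]].copy()
        rng = np.random.default_rng(3)
        drop = rng.choice(12, size=4, replace=False)
        cell.iloc[0, drop] = np.nan
        got = project(model, cell).to_numpy()[0]
        want = model.scores.iloc[0].to_numpy()
        assert np.linalg.norm(got - want) < 0.3 * model.scores.std().mean() * 3

    def test_cell_with_nothing_observed_gets_nan(self, block_model):
        m, model = block_model
        cell = m.iloc[[0]].copy()
        cell.iloc[0, :] = np.nan
        assert np.isnan(project(model, cell).to_numpy()).all()


class TestImputation:
    def test_complete_matrix_returned_unchanged(self, rng):
        m = pd.DataFrame(rng.standard_normal((30, 5)))
        for frame in impute(m, n_imputations=3, seed=0):
            np.testing.assert_allclose(frame.to_numpy(), m.to_numpy(), atol=1e-12)

    def test_between_imputation_variance_positive(self, rng):
        m = apply_missingness(pd.DataFrame(rng.standard_normal((40, 6))), 0.2, seed=1)
        frames = impute(m, n_imputations=5, seed=0)
        mask = m.isna().to_numpy()
        stack = np.stack([f.to_numpy() for f in frames])
        assert (stack.std(axis=0)[mask] > 0).all()

    def test_imputation_beats_marginal_baseline(self, rng):
        # correlated columns: conditional imputation must beat the marginal SD
        w = rng.normal(size=(8, 2))
        truth = rng.standard_normal((120, 2)) @ w.T + 0.3 * rng.standard_normal((120, 8))
        full = pd.DataFrame(truth)
        masked = apply_missingness(full, 0.2, seed=2)
        frames = impute(masked, n_imputations=10, seed=0)
        mask = masked.isna().to_numpy()
        est = np.mean([f.to_numpy() for f in frames], axis=0)
        rmse = np.sqrt(np.mean((est[mask] - truth[mask])**2))
        marginal = np.sqrt(np.mean((full.to_numpy().mean(0)[None, :]
                                    .repeat(120, 0)[mask] - truth[mask])**2))
        assert rmse < marginal

    def test_reproducible_per_index(self, rng):
        m = apply_missingness(pd.DataFrame(rng.standard_normal((30, 5))), 0.2, seed=3)
        a = impute(m, n_imputations=3, seed=7)
        b = impute(m, n_imputations=3, seed=7)
        for fa, fb in zip(a, b):
            pd.testing.assert_frame_equal(fa, fb)


class TestCloudGeometry:
    def test_unit_square_median(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        assert cloud_median_distance(pts) == pytest.approx(1.0)

    def test_homogeneity_under_scaling(self, rng):
        pts = rng.standard_normal((40, 3))
        assert cloud_median_distance(2 * pts) == pytest.approx(
            2 * cloud_median_distance(pts))

    def test_sd_ratio_shows_in_median_ratio(self, rng):
        # single-draw medians are noisy; the ratio concentrates over subsamples
        ratios = []
        for _ in range(12):
            a = rng.standard_normal((200, 5))
            b = 1.4 * rng.standard_normal((200, 5))
            ratios.append(cloud_median_distance(b) / cloud_median_distance(a))
        assert np.mean(ratios) == pytest.approx(1.4, abs=0.05)


class TestAgnes:
    def test_matches_reference_implementation(self):
        # frozen oracle values from R cluster::agnes (average linkage)
        rng = np.random.default_rng(42)
        blobs = np.vstack([rng.normal(0, 0.5, size=(8, 3)),
                           rng.normal(5, 0.5, size=(7, 3))])
        assert agnes_coefficient(blobs) == pytest.approx(0.9297635816, abs=1e-8)
        diffuse = rng.normal(0, 1, size=(12, 4))
        assert agnes_coefficient(diffuse) == pytest.approx(0.6066399248, abs=1e-8)

    def test_tight_separated_blobs_near_one(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, size=(10, 2)),
                         rng.normal(10, 0.01, size=(10, 2))])
        assert agnes_coefficient(pts) > 0.95

    def test_equilateral_triangle_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        assert agnes_coefficient(pts) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariant(self, rng):
        pts = rng.standard_normal((15, 3))
        assert agnes_coefficient(pts) == pytest.approx(
            agnes_coefficient(5.0 * pts), abs=1e-12)

    def test_monotone_in_cluster_separation(self, rng):
        base = rng.standard_normal((20, 2))
        shift = np.zeros((20, 2))
        shift[10:, 0] = 1.0
        vals = [agnes_coefficient(base + s * shift) for s in (0.0, 3.0, 8.0, 20.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestLocalPCA:
    def test_planar_data_fully_explained(self, rng):
        f = rng.standard_normal((50, 2))
        load = rng.normal(size=(8, 2))
        pts = f @ load.T
        assert local_pca_variance(pts) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_share_modest(self, rng):
        pts = rng.standard_normal((50, 33))
        share = local_pca_variance(pts)
        assert 2 / 33 < share < 0.25

    def test_correlation_structure_raises_share(self, rng):
        iso = rng.standard_normal((60, 10))
        common = rng.standard_normal((60, 1))
        mixed = iso + 1.5 * common
        assert local_pca_variance(mixed) > local_pca_variance(iso)


class TestOrdinationQuality:
    def test_perfect_when_full_space_is_planar(self, rng):
        pts = rng.standard_normal((30, 2))
        assert ordination_quality(pts, pts) == pytest.approx(1.0)

    def test_random_coords_explain_little(self, rng):
        full = synth_feature_matrix(100, 20, n_factors=2, seed=0).to_numpy()
        rand = rng.standard_normal((100, 2))
        assert ordination_quality(rand, full) < 0.1

    def test_pca_beats_random_projection(self, rng):
        from sklearn.decomposition import PCA
        full = synth_feature_matrix(100, 20, n_factors=2, seed=1).to_numpy()
        pca_coords = PCA(2).fit_transform(full)
        rand_coords = full @ rng.standard_normal((20, 2))
        assert (ordination_quality(pca_coords, full)
                >= ordination_quality(rand_coords, full))


class TestGroupCompare:
    def test_identical_groups_not_flagged(self, rng):
        vals = rng.standard_normal(60)
        m = pd.DataFrame({"v": np.concatenate([vals, vals])})
        groups = ["a"] * 60 + ["b"] * 60
        out = group_compare(m, groups)
        assert out.loc["v", "p_mw"] > 0.9
        assert out.loc["v", "eta_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_shifted_groups_strongly_flagged(self, rng):
        m = pd.DataFrame({"v": np.concatenate([rng.normal(0, 1, 50),
                                               rng.normal(2, 1, 50)])})
        out = group_compare(m, ["a"] * 50 + ["b"] * 50)
        assert out.loc["v", "p_mw"] < 1e-6
        assert out.loc["v", "eta_sq"] > 0.3

    def test_variance_ratio_power_at_forty_percent_inflation(self, rng):
        # directional screen for inflated variability at n = 60 per group
        # (exact power of the one-sided F-test here is 0.8215)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            a = rng.standard_normal(60)
            b = 1.4 * rng.standard_normal(60)
            _, p = variance_ratio_test(a, b, alternative="greater")
            hits += p < 0.05
        assert hits / n_sim > 0.80

    def test_sparse_variable_skipped(self, rng):
        m = pd.DataFrame({"v": [1.0, np.nan, np.nan, 2.0, 3.0, 4.0]})
        out = group_compare(m, ["a", "a", "a", "b", "b", "b"], min_n=3)
        assert "p_mw" not in out.columns or np.isnan(out.loc["v"].get("p_mw", np.nan))


class TestSequentialRegression:
    def test_exact_linear_response_fully_partitioned(self, rng):
        x = rng.standard_normal((60, 3))
        y = 2 * x[:, 0] - x[:, 1]
        m = pd.DataFrame(np.column_stack([y, x]), columns=["y", "a", "b", "c"])
        out = sequential_regression(m, "y", ["a", "b", "c"])
        assert out.loc[["a", "b"], "share"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out.loc["c", "share"] == pytest.approx(0.0, abs=1e-9)

    def test_noise_response_explains_nothing(self, rng):
        m = pd.DataFrame(rng.standard_normal((200, 5)),
                         columns=["y", "a", "b", "c", "d"])
        out = sequential_regression(m, "y", ["a", "b", "c", "d"])
        assert out["share"].sum() < 0.10

    def test_interaction_only_response(self, rng):
        x = rng.standard_normal((150, 2))
        y = x[:, 0] * x[:, 1]
        m = pd.DataFrame(np.column_stack([y, x]), columns=["y", "a", "b"])
        out = sequential_regression(m, "y", ["a", "b"], include_interactions=True)
        assert out.loc["a:b", "share"] > 0.8
        assert out.loc[["a", "b"], "share"].sum() < 0.1

    def test_collinear_term_dropped(self, rng):
        x = rng.standard_normal(50)
        m = pd.DataFrame({"y": x + rng.standard_normal(50), "a": x, "b": x})
        with pytest.warns(UserWarning):
            out = sequential_regression(m, "y", ["a", "b"])
        assert "b" not in out.index


class TestRankRenormalize:
    def test_order_strictly_preserved(self, rng):
        v = rng.standard_normal(50)
        out = rank_renormalize(v)
        rho, _ = sps.spearmanr(v, out)
        assert rho == pytest.approx(1.0)

    def test_monotone_input_nearly_unchanged(self):
        v = np.linspace(-40.0, -20.0, 25)
        out = rank_renormalize(v)
        np.testing.assert_allclose(out, v, atol=0.5)

    def test_banded_input_debanded(self, rng):
        bands = np.repeat([-40.0, -30.0, -20.0], 20) + rng.normal(0, 0.1, 60)
        out = rank_renormalize(bands)

        def ks_to_uniform(x):
            u = (x - x.min()) / np.ptp(x)
            return sps.kstest(u, "uniform").statistic

        assert ks_to_uniform(out) < ks_to_uniform(bands)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            rank_renormalize([1.0, 2.0, 3.0])


class TestCloudSizePipeline:
    def test_inflation_detected_by_full_procedure(self):
        # one population split in two, the second group 22% larger in spread
        pop = synth_feature_matrix(120, 33, n_factors=2, seed=21)
        a = apply_missingness(pop.iloc[:64], 0.18, seed=1)
        b = apply_missingness(pop.iloc[64:] * 1.22, 0.18, seed=2)
        res = compare_cloud_sizes(a, b, n_imputations=10, n_subsamples=5,
                                  subsample_size=40, seed=0)
        assert res["p"] < 0.01
        assert res["ratio"] > 1.0


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=4, max_size=30,
                unique=True))
def test_rank_renormalize_is_order_preserving_property(values):
    out = rank_renormalize(np.asarray(values))
    order_in = np.argsort(values, kind="stable")
    assert (np.diff(out[order_in]) > 0).all()
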