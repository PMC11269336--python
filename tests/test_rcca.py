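"""Regularized CCA: oracle equivalence, invariances, loadings, projection
and cross-validated hyperparameter selection."""

import numpy as np
import pytest

from neurocca import (
    RCCAConfig,
    compute_loadings,
    fit_rcca,
    generate_cohort,
    grid_search_cv,
    hbn_like_spec,
    make_blocks,
    project,
)


class TestFit:
    def test_identical_blocks_give_unit_correlations(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        m = fit_rcca(X, X.copy(), k=4, reg=1e-8)
        np.testing.assert_allclose(m.canonical_correlations, 1.0, atol=1e-6)

    def test_matches_classical_oracle_at_vanishing_reg(self, gaussian_pair, oracle):
        X, Y = gaussian_pair
        m = fit_rcca(X, Y, k=3, reg=1e-8)
        np.testing.assert_allclose(m.canonical_correlations, oracle(X, Y)[:3], atol=1e-6)

    def test_orthogonal_blocks_give_zero_correlations(self):
        # construct exact zero sample cross-covariance
        rng = np.random.default_rng(1)
        n = 40
        M = rng.standard_normal((n, 7))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))
        X, Y = Q[:, :4], Q[:, 4:7]
        m = fit_rcca(X, Y, k=3, reg=1e-6)
        np.testing.assert_allclose(m.canonical_correlations, 0.0, atol=1e-10)

    def test_reported_correlation_is_pearson_of_variates(self, planted_blocks):
        b = planted_blocks
        m = fit_rcca(b.X, b.Y, k=2, reg=0.01)
        for i in range(2):
            r = np.corrcoef(m.x_variates[:, i], m.y_variates[:, i])[0, 1]
            assert abs(r - m.canonical_correlations[i]) < 1e-8

    def test_variates_unit_variance_and_sorted_correlations(self, planted_blocks):
        m = fit_rcca(planted_blocks.X, planted_blocks.Y, k=3, reg=0.01)
        np.testing.assert_allclose(m.x_variates.std(axis=0, ddof=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(m.y_variates.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert (np.diff(m.canonical_correlations) <= 1e-12).all()

    def test_sign_convention_largest_x_loading_positive(self, planted_blocks):
        m = fit_rcca(planted_blocks.X, planted_blocks.Y, k=2, reg=1e-4)
        for i in range(m.k):
            assert m.x_loadings[np.abs(m.x_loadings[:, i]).argmax(), i] > 0

    def test_shrinkage_reduces_first_correlation(self, planted_blocks):
        b = planted_blocks
        low = fit_rcca(b.X, b.Y, k=2, reg=1e-4).canonical_correlations[0]
        high = fit_rcca(b.X, b.Y, k=2, reg=100.0).canonical_correlations[0]
        assert high <= low + 1e-8

    def test_scale_invariance_at_vanishing_reg(self, gaussian_pair):
        X, Y = gaussian_pair
        ref = fit_rcca(X, Y, k=3, reg=1e-10).canonical_correlations
        X2 = X * np.array([3.0, 0.5, 10.0, 1.0])
        scaled = fit_rcca(X2, Y, k=3, reg=1e-10).canonical_correlations
        np.testing.assert_allclose(scaled, ref, atol=1e-8)

    def test_joint_row_permutation_equivariance(self, gaussian_pair):
        X, Y = gaussian_pair
        perm = np.random.default_rng(3).permutation(len(X))
        ref = fit_rcca(X, Y, k=2, reg=0.01)
        shuf = fit_rcca(X[perm], Y[perm], k=2, reg=0.01)
        np.testing.assert_allclose(shuf.canonical_correlations,
                                   ref.canonical_correlations, atol=1e-10)

    def test_invalid_inputs_rejected(self, gaussian_pair):
        X, Y = gaussian_pair
        with pytest.raises(ValueError, match="k="):
            fit_rcca(X, Y, k=4, reg=1e-4)          # q = 3 < k
        with pytest.raises(ValueError, match="non-finite"):
            fit_rcca(np.full_like(X, np.nan), Y, k=1, reg=1e-4)
        with pytest.raises(ValueError, match="reg"):
            fit_rcca(X, Y, k=1, reg=-1.0)


class TestLoadings:
    def test_bounded_by_one(self, planted_blocks):
        m = fit_rcca(planted_blocks.X, planted_blocks.Y, k=3, reg=0.01)
        assert np.abs(m.x_loadings).max() <= 1 + 1e-12
        assert np.abs(m.y_loadings).max() <= 1 + 1e-12

    def test_single_variable_block_loading_is_unit(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 3))
        y = (X @ [1.0, 0.5, 0.0] + rng.standard_normal(50))[:, None]
        m = fit_rcca(X, y, k=1, reg=1e-8)
        assert abs(abs(m.y_loadings[0, 0]) - 1) < 1e-10

    def test_planted_direction_recovered(self):
        """X-loading pattern aligns with the planted anatomical direction."""
        spec = hbn_like_spec(n_subjects=30_000, latent_corrs=(0.5,), seed=5,
                             confounds=False)
        blocks = make_blocks(generate_cohort(spec))
        m = fit_rcca(blocks.X, blocks.Y, k=1, reg=1e-4)
        planted = np.asarray(spec.x_loadvecs)[0]
        load = m.x_loadings[:, 0]
        cos = abs(planted @ load) / np.linalg.norm(planted) / np.linalg.norm(load)
        assert cos > 0.98

    def test_zero_variance_variate_rejected(self):
        X = np.random.default_rng(6).standard_normal((20, 2))
        with pytest.raises(ValueError, match="zero-variance"):
            compute_loadings(X, np.zeros((20, 1)), X, np.ones((20, 1)))


class TestProject:
    def test_training_data_reproduces_stored_variates(self, planted_blocks):
        b = planted_blocks
        m = fit_rcca(b.X, b.Y, k=2, reg=1e-4)
        xv, yv = project(m, b.X, b.Y)
        np.testing.assert_allclose(xv, m.x_variates, atol=1e-10)
        np.testing.assert_allclose(yv, m.y_variates, atol=1e-10)

    def test_row_permutation_permutes_variates(self, planted_blocks):
        b = planted_blocks
        m = fit_rcca(b.X, b.Y, k=2, reg=1e-4)
        perm = np.random.default_rng(7).permutation(b.X.shape[0])
        xv, _ = project(m, b.X[perm], b.Y[perm])
        np.testing.assert_allclose(xv, m.x_variates[perm], atol=1e-10)

    def test_column_mismatch_rejected(self, planted_blocks):
        b = planted_blocks
        m = fit_rcca(b.X, b.Y, k=2, reg=1e-4)
        with pytest.raises(ValueError, match="column mismatch"):
            project(m, b.X[:, :5], b.Y)

    def test_holdout_correlation_near_planted_value(self):
        table = generate_cohort(hbn_like_spec(
            n_subjects=20_000, latent_corrs=(0.4,), seed=8, confounds=False))
        blocks = make_blocks(table)
        half = 10_000
        m = fit_rcca(blocks.X[:half], blocks.Y[:half], k=1, reg=1e-4)
        xv, yv = project(m, blocks.X[half:], blocks.Y[half:])
        r = np.corrcoef(xv[:, 0], yv[:, 0])[0, 1]
        assert abs(abs(r) - 0.4) < 0.05


class TestGridSearch:
    def test_single_cell_grid_returned(self, planted_blocks):
        res = grid_search_cv(planted_blocks.X, planted_blocks.Y,
                             RCCAConfig(n_components_grid=(2,), reg_grid=(0.01,)))
        assert (res.best_k, res.best_reg) == (2, 0.01)
        assert len(res.cv_table) == 1

    def test_empty_grid_rejected(self, planted_blocks):
        with pytest.raises(ValueError, match="non-empty"):
            grid_search_cv(planted_blocks.X, planted_blocks.Y,
                           RCCAConfig(n_components_grid=()))

    def test_deterministic_given_seed(self, planted_blocks):
        cfg = RCCAConfig(seed=123)
        a = grid_search_cv(planted_blocks.X, planted_blocks.Y, cfg)
        b = grid_search_cv(planted_blocks.X, planted_blocks.Y, cfg)
        assert a.cv_table.equals(b.cv_table)

    def test_two_planted_latents_select_k2(self):
        """With two strong planted components at the study sample size, the
        default grids select k = 2 in at least 90% of seeds."""
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            table = generate_cohort(hbn_like_spec(
                n_subjects=662, latent_corrs=(0.6, 0.4), seed=900 + s))
            blocks = make_blocks(table)
            res = grid_search_cv(blocks.X, blocks.Y, RCCAConfig(seed=s))
            hits += res.best_k == 2
        assert hits >= int(0.9 * n_seeds)
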