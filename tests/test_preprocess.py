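"""Standardization, residualization, VIF and the pairwise screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocca import (
    build_confound_design,
    compute_vif,
    effect_size_label,
    fit_rcca,
    generate_cohort,
    hbn_like_spec,
    make_blocks,
    pairwise_screen,
    residualize,
    zscore_columns,
)


class TestZscore:
    def test_basic_column(self):
        out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1) < 1e-12

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        Z = zscore_columns(rng.standard_normal((40, 3)))
        np.testing.assert_allclose(zscore_columns(Z), Z, atol=1e-12)

    def test_constant_column_error_names_column(self):
        M = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="icv"):
            zscore_columns(M, names=["age", "icv"])

    def test_cohort_columns_standardize(self):
        table = generate_cohort(hbn_like_spec(n_subjects=500, seed=1))
        cols = [c for c in table.columns if c not in ("subject_id", "sex", "site")]
        Z = zscore_columns(table[cols].to_numpy())
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0, ddof=1) - 1).max() < 1e-10


class TestResidualize:
    def _design(self, n, rng):
        return np.column_stack([np.ones(n), rng.standard_normal((n, 2))])

    def test_orthogonal_input_unchanged(self):
        rng = np.random.default_rng(1)
        C = self._design(60, rng)
        M = rng.standard_normal((60, 3))
        M_orth = M - C @ np.linalg.lstsq(C, M, rcond=None)[0]
        np.testing.assert_allclose(residualize(M_orth, C), M_orth, atol=1e-10)

    def test_exact_linear_function_gives_zero(self):
        rng = np.random.default_rng(2)
        C = self._design(50, rng)
        M = C @ rng.standard_normal((3, 4))
        assert np.abs(residualize(M, C)).max() < 1e-10

    def test_projection_idempotent(self):
        rng = np.random.default_rng(3)
        C = self._design(80, rng)
        M = rng.standard_normal((80, 5))
        R = residualize(M, C)
        np.testing.assert_allclose(residualize(R, C), R, atol=1e-12)

    def test_rank_deficient_design_lists_columns(self):
        n = 30
        C = np.column_stack([np.ones(n), np.arange(n, dtype=float),
                             2 * np.arange(n, dtype=float)])
        with pytest.raises(ValueError, match="age_x2"):
            residualize(np.random.default_rng(0).standard_normal((n, 2)), C,
                        confound_names=["intercept", "age", "age_x2"])

    def test_cohort_residuals_orthogonal_to_age(self):
        table = generate_cohort(hbn_like_spec(n_subjects=662, seed=4))
        blocks = make_blocks(table)
        age = table["age"].to_numpy() - table["age"].mean()
        n = len(table)
        for M in (blocks.X, blocks.Y):
            assert np.abs(age @ M / n).max() < 1e-10


class TestVIF:
    def test_orthonormal_columns_give_exactly_one(self):
        Q, _ = np.linalg.qr(np.random.default_rng(5).standard_normal((50, 4)))
        vif = compute_vif(Q)
        np.testing.assert_array_equal(vif["vif"].to_numpy(), np.ones(4))
        assert not vif["flagged"].any()

    def test_duplicate_columns_flagged_infinite(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        M = np.column_stack([x, x, rng.standard_normal(40)])
        vif = compute_vif(M)
        assert np.isinf(vif["vif"].iloc[0]) and np.isinf(vif["vif"].iloc[1])
        assert vif["flagged"].iloc[0] and vif["flagged"].iloc[1]

    def test_known_r_squared_gives_vif_four(self):
        # column 3 = sqrt(3)*z1 + unit noise, all centered & orthogonal by
        # construction -> R^2 = 3/4 exactly, VIF = 4
        n = 64
        rng = np.random.default_rng(7)
        basis, _ = np.linalg.qr(rng.standard_normal((n, 3)))
        z1, z2, e = basis.T * np.sqrt(n - 1)     # orthogonal, norm sqrt(n-1)
        col3 = np.sqrt(3.0) * z1 + e
        M = np.column_stack([z1, z2, col3])
        vif = compute_vif(M)
        assert vif["vif"].iloc[2] == pytest.approx(4.0, abs=1e-9)

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        rng = np.random.default_rng(8)
        base = rng.standard_normal((200, 3))
        M = np.column_stack([base, base @ [0.5, 0.4, 0.0] + rng.standard_normal(200)])
        M = M - M.mean(axis=0)
        ours = compute_vif(M)["vif"].to_numpy()
        theirs = [variance_inflation_factor(M, j) for j in range(4)]
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)


class TestPairwiseScreen:
    def test_labels_and_self_correlation(self):
        assert effect_size_label(1.0) == "large"
        assert effect_size_label(0.35) == "moderate"
        assert effect_size_label(-0.12) == "small"
        assert effect_size_label(0.05) == "negligible"

    def test_null_cohort_cognition_cbcl_uncorrelated(self):
        n = 5000
        table = generate_cohort(hbn_like_spec(n_subjects=n, seed=9, confounds=False))
        screen = pairwise_screen(table)
        cbcl_rows = screen[(screen["var_a"] == "cbcl_total") | (screen["var_b"] == "cbcl_total")]
        assert (cbcl_rows["r"].abs() < 4 / np.sqrt(n)).all()

    def test_too_few_rows_rejected(self):
        table = generate_cohort(hbn_like_spec(n_subjects=30, seed=0)).head(2)
        with pytest.raises(ValueError, match="3 rows"):
            pairwise_screen(table)


def test_scaling_order_leaves_canonical_correlations_unchanged():
    """Z-score -> residualize vs residualize -> Z-score: CCA is invariant to
    per-column affine rescaling, so both orders give the same correlations."""
    table = generate_cohort(hbn_like_spec(n_subjects=400, latent_corrs=(0.4,), seed=10))
    design, _ = build_confound_design(table)
    X_raw = table.iloc[:, 4:13].to_numpy(dtype=float)
    Y_raw = table.iloc[:, 13:17].to_numpy(dtype=float)
    a = [zscore_columns(residualize(zscore_columns(M), design)) for M in (X_raw, Y_raw)]
    b = [residualize(M, design) for M in (X_raw, Y_raw)]
    ca = fit_rcca(a[0], a[1], k=2, reg=1e-10).canonical_correlations
    cb = fit_rcca(b[0], b[1], k=2, reg=1e-10).canonical_correlations
    np.testing.assert_allclose(ca, cb, atol=1e-8)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.integers(min_value=10, max_value=60))
def test_residualization_projection_property(seed, n):
    """Residualization is an orthogonal projection: idempotent, and the
    output is orthogonal to every confound column."""
    rng = np.random.default_rng(seed)
    C = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
    M = rng.standard_normal((n, 4))
    R = residualize(M, C)
    assert np.abs(C.T @ R / n).max() < 1e-10
    np.testing.assert_allclose(residualize(R, C), R, atol=1e-10)
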