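import numpy as np
import pytest
import scipy.linalg as la

from neurocca import generate_cohort, hbn_like_spec, make_blocks


def classical_cca_corrs(X, Y):
    """Independent brute-force oracle: SVD of the whitened cross-covariance
    of centered blocks (no regularization, matrix fractional powers)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    n = len(X)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    Wx = la.fractional_matrix_power(Sxx, -0.5).real
    Wy = la.fractional_matrix_power(Syy, -0.5).real
    return la.svd(Wx @ Sxy @ Wy, compute_uv=False)


@pytest.fixture(scope="session")
def oracle():
    return classical_cca_corrs


@pytest.fixture(scope="session")
def planted_blocks():
    """Residualized blocks from a cohort with one planted canonical
    correlation of 0.5 at the study's sample size, confounds on."""
    table = generate_cohort(hbn_like_spec(latent_corrs=(0.5,), seed=42))
    return make_blocks(table)


@pytest.fixture(scope="session")
def null_blocks():
    """Residualized blocks from a confound-contaminated cohort with no
    cross-block structure."""
    table = generate_cohort(hbn_like_spec(latent_corrs=(0.0, 0.0), seed=43))
    return make_blocks(table)


@pytest.fixture(scope="session")
def gaussian_pair():
    rng = np.random.default_rng(7)
    return rng.standard_normal((50, 4)), rng.standard_normal((50, 3))
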