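"""Permutation significance testing and bootstrap stability analysis.

Significance: rows of Y are randomly permuted (X and the confound
structure fixed), the model is refit with the hyperparameters frozen at
their observed-data selection, and the canonical correlations are
collected into a null distribution; the per-component threshold is its
95th percentile and p-values use the add-one correction
``(#{null >= observed} + 1) / (n_perm + 1)``.

Stability: subjects are resampled with replacement, the model refit, and
each bootstrap solution aligned to the original to resolve component
order and sign indeterminacy before aggregation. Alignment restricts to
signed permutations by default (full orthogonal Procrustes available),
chosen by maximizing the per-component cosine between the concatenated
(X; Y) loading matrices. Confidence intervals are reported both as
percentile [2.5, 97.5] intervals (default criterion for stability) and as
bootstrap mean +/- 1.96 SD; the bootstrap ratio is the original-sample
loading divided by the bootstrap SD of the aligned loadings, a pseudo-z
stability index. A component is "stable" when its correlation CI excludes
zero. Note the bootstrap distribution of an in-sample canonical
correlation is upward-biased relative to the population value; it
measures sampling stability, not out-of-sample effect size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import linear_sum_assignment

from .rcca import RCCAModel, _column_corr, _fit_core, _inv_sqrt_psd, compute_loadings, fit_rcca

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "AlignmentRecord",
    "permutation_test",
    "bootstrap_stability",
    "align_solution",
]

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed_corrs: np.ndarray   # k
    null_corrs: np.ndarray       # n_perm x k
    thresholds: np.ndarray       # per-component 1-alpha empirical quantile
    p_values: np.ndarray         # add-one corrected
    n_perm: int
    alpha: float
    seed: int
    warnings: list = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return self.p_values <= self.alpha


@dataclass
class AlignmentRecord:
    method: str
    permutation: np.ndarray | None = None
    signs: np.ndarray | None = None
    rotation: np.ndarray | None = None
    degenerate: bool = False


@dataclass
class BootstrapResult:
    observed_corrs: np.ndarray
    boot_corrs: np.ndarray          # n_boot x k (alignment-permuted)
    boot_x_loadings: np.ndarray     # n_boot x p x k (aligned)
    boot_y_loadings: np.ndarray     # n_boot x q x k
    ci_low: dict                    # {"corrs": k, "x_loadings": p x k, "y_loadings": q x k}
    ci_high: dict
    sd_ci_low: dict                 # boot mean +/- 1.96 SD form
    sd_ci_high: dict
    bootstrap_ratios: dict          # {"x_loadings", "y_loadings"}
    stable_flags: np.ndarray        # per component, percentile corr CI excludes 0
    n_boot: int
    seed: int
    n_redraws: int = 0


def _permutation_fast_path(Xc, Yc, k, reg):
    """Precompute whiteners: Sxx and Syy are invariant under row permutation
    of Y, so only the cross-covariance SVD must be redone per draw. Returns a
    closure mapping a permutation to correlation-sorted canonical
    correlations, numerically identical to a full refit."""
    n, p = Xc.shape
    q = Yc.shape[1]
    Sxx = (Xc.T @ Xc) / (n - 1) + reg * np.eye(p)
    Syy = (Yc.T @ Yc) / (n - 1) + reg * np.eye(q)
    Wx = _inv_sqrt_psd(Sxx, "X")
    Wy = _inv_sqrt_psd(Syy, "Y")
    Kx = Xc @ Wx
    Ky = Yc @ Wy
    A = (Kx.T @ Kx) / (n - 1)   # whitened true covariances (no reg)
    B = (Ky.T @ Ky) / (n - 1)

    def corrs_for(perm: np.ndarray) -> np.ndarray:
        M = (Kx.T @ Ky[perm]) / (n - 1)
        U, s, Vt = linalg.svd(M, full_matrices=False)
        U, V = U[:, :k], Vt[:k].T
        den = np.sqrt(np.einsum("ij,jl,li->i", U.T, A, U)
                      * np.einsum("ij,jl,li->i", V.T, B, V))
        r = s[:k] / den
        return np.sort(r)[::-1]

    return corrs_for


def permutation_test(X, Y, k: int, reg: float, n_perm: int = 10000,
                     alpha: float = 0.05, seed: int = 0) -> PermutationResult:
    """Permutation null distribution of the canonical correlations.

    Hyperparameters ``(k, reg)`` are frozen (selected on the observed data
    before calling); re-selection inside the loop is deliberately not done
    here — wrap :func:`neurocca.rcca.grid_search_cv` per draw if that
    variant is wanted.
    """
    warns = []
    if n_perm < 100:
        msg = f"n_perm={n_perm} is very small; p-value resolution is 1/{n_perm + 1}"
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)
    model = fit_rcca(X, Y, k=k, reg=reg)
    observed = model.canonical_correlations
    Xc = np.asarray(X, float) - np.asarray(X, float).mean(axis=0)
    Yc = np.asarray(Y, float) - np.asarray(Y, float).mean(axis=0)
    corrs_for = _permutation_fast_path(Xc, Yc, k, reg)
    rng = np.random.default_rng(seed)
    n = Xc.shape[0]
    null = np.empty((n_perm, k))
    for b in range(n_perm):
        null[b] = corrs_for(rng.permutation(n))
    exceed = (null >= observed).sum(axis=0)
    return PermutationResult(
        observed_corrs=observed, null_corrs=null,
        thresholds=np.quantile(null, 1.0 - alpha, axis=0),
        p_values=(exceed + 1) / (n_perm + 1),
        n_perm=n_perm, alpha=alpha, seed=seed, warnings=warns,
    )


def align_solution(ref_loadings, boot_loadings, method: str = "signed_permutation"):
    """Resolve component order/sign indeterminacy of a resampled solution.

    Both arguments are (p+q) x k concatenated (X; Y) loading matrices. The
    default searches signed permutations for maximal mean per-component
    cosine with the reference (optimal assignment on the absolute cosine
    matrix); ``method="procrustes"`` applies the full orthogonal Procrustes
    rotation instead. Returns ``(aligned, AlignmentRecord)``.
    """
    ref = np.asarray(ref_loadings, dtype=float)
    boot = np.asarray(boot_loadings, dtype=float)
    if ref.shape != boot.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {boot.shape}")
    k = ref.shape[1]
    bnorm = np.linalg.norm(boot, axis=0)
    rnorm = np.linalg.norm(ref, axis=0)
    if (bnorm == 0).any() or (rnorm == 0).any():
        return boot.copy(), AlignmentRecord(
            method=method, permutation=np.arange(k), signs=np.ones(k), degenerate=True
        )
    if method == "procrustes":
        R, _ = linalg.orthogonal_procrustes(boot, ref)
        return boot @ R, AlignmentRecord(method=method, rotation=R)
    if method != "signed_permutation":
        raise ValueError(f"unknown alignment method {method!r}")
    C = (ref / rnorm).T @ (boot / bnorm)       # k x k cosine matrix
    ref_idx, boot_idx = linear_sum_assignment(-np.abs(C))
    perm = np.empty(k, dtype=int)
    perm[ref_idx] = boot_idx
    signs = np.sign(C[np.arange(k), perm])
    signs[signs == 0] = 1.0
    return boot[:, perm] * signs, AlignmentRecord(
        method=method, permutation=perm, signs=signs
    )


def bootstrap_stability(X, Y, k: int, reg: float, n_boot: int = 10000,
                        seed: int = 0, align_method: str = "signed_permutation",
                        max_redraws: int = 10) -> BootstrapResult:
    """Bootstrap the fitted model: resample subjects with replacement, refit,
    align each solution to the original, and aggregate correlations and
    structure coefficients."""
    ref = fit_rcca(X, Y, k=k, reg=reg)
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    n, p = Xa.shape
    q = Ya.shape[1]
    ref_concat = np.vstack([ref.x_loadings, ref.y_loadings])
    rng = np.random.default_rng(seed)

    boot_corrs = np.empty((n_boot, k))
    boot_xl = np.empty((n_boot, p, k))
    boot_yl = np.empty((n_boot, q, k))
    n_redraws = 0
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            Xb = Xa[idx]
            Yb = Ya[idx]
            if Xb.std(axis=0).min() > 0 and Yb.std(axis=0).min() > 0:
                break
            n_redraws += 1
            logger.info("bootstrap draw %d produced a constant column; redrawn", b)
        else:
            raise RuntimeError(
                f"bootstrap draw {b}: constant column persisted after {max_redraws} redraws"
            )
        Xbc = Xb - Xb.mean(axis=0)
        Ybc = Yb - Yb.mean(axis=0)
        a, w, corrs = _fit_core(Xbc, Ybc, k, reg)
        xl, yl = compute_loadings(Xbc, Xbc @ a, Ybc, Ybc @ w)
        aligned, rec = align_solution(ref_concat, np.vstack([xl, yl]), method=align_method)
        boot_xl[b] = aligned[:p]
        boot_yl[b] = aligned[p:]
        if rec.permutation is not None:
            boot_corrs[b] = corrs[rec.permutation]
        else:
            boot_corrs[b] = corrs

    def pct(arr, qtl):
        return np.quantile(arr, qtl, axis=0)

    ci_low = {"corrs": pct(boot_corrs, 0.025), "x_loadings": pct(boot_xl, 0.025),
              "y_loadings": pct(boot_yl, 0.025)}
    ci_high = {"corrs": pct(boot_corrs, 0.975), "x_loadings": pct(boot_xl, 0.975),
               "y_loadings": pct(boot_yl, 0.975)}
    sd_low, sd_high = {}, {}
    for key, arr in (("corrs", boot_corrs), ("x_loadings", boot_xl), ("y_loadings", boot_yl)):
        mu = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
        sd_low[key] = mu - 1.96 * sd
        sd_high[key] = mu + 1.96 * sd
    ratios = {
        "x_loadings": ref.x_loadings / boot_xl.std(axis=0, ddof=1),
        "y_loadings": ref.y_loadings / boot_yl.std(axis=0, ddof=1),
    }
    stable = (ci_low["corrs"] > 0) | (ci_high["corrs"] < 0)
    return BootstrapResult(
        observed_corrs=ref.canonical_correlations, boot_corrs=boot_corrs,
        boot_x_loadings=boot_xl, boot_y_loadings=boot_yl,
        ci_low=ci_low, ci_high=ci_high, sd_ci_low=sd_low, sd_ci_high=sd_high,
        bootstrap_ratios=ratios, stable_flags=stable,
        n_boot=n_boot, seed=seed, n_redraws=n_redraws,
    )
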