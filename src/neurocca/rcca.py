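"""Regularized linear-kernel canonical correlation analysis.

With a linear kernel and p, q << n the kernel formulation is solved in
feature space: the block covariances are ridge-shrunk, ``C_xx = S_xx +
reg * I`` (and likewise for Y), and the canonical weight pairs come from
the SVD of the whitened cross-covariance ``C_xx^{-1/2} S_xy C_yy^{-1/2}``.
On Z-scored data (unit-diagonal covariance) ``reg`` is therefore directly
interpretable as a ridge on the correlation scale, which is what makes the
conventional grid [1e-4, 1e-2, 1, 100] meaningful: 1e-4 is essentially
classical CCA, 100 is essentially cross-covariance (PLS-like) shrinkage.

Reported canonical correlations are always the realized Pearson
correlations between paired variates (identical to the singular values as
reg -> 0). Variates are scaled to unit variance, components are ordered by
decreasing realized correlation, and each component's sign is fixed so
that its largest-magnitude anatomical loading is positive — the bootstrap
alignment step depends on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.model_selection import KFold

__all__ = [
    "RCCAConfig",
    "RCCAModel",
    "fit_rcca",
    "compute_loadings",
    "project",
    "grid_search_cv",
    "GridSearchResult",
]


@dataclass
class RCCAConfig:
    """Hyperparameter grids and cross-validation settings."""

    n_components_grid: tuple[int, ...] = (2, 3, 4)
    reg_grid: tuple[float, ...] = (0.0001, 0.01, 1.0, 100.0)
    kernel: str = "linear"
    cv_folds: int = 10
    selection_metric: str = "mean_holdout_corr"  # or sum_holdout_corr / first_component_corr
    seed: int = 0

    def validate(self) -> None:
        if not self.n_components_grid or not self.reg_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(k < 1 for k in self.n_components_grid):
            raise ValueError("n_components must be >= 1")
        if any(r < 0 for r in self.reg_grid):
            raise ValueError("reg values must be nonnegative")
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.selection_metric not in (
            "mean_holdout_corr", "sum_holdout_corr", "first_component_corr"
        ):
            raise ValueError(f"unknown selection_metric {self.selection_metric!r}")


@dataclass
class RCCAModel:
    """Fitted model: weights, variates, correlations, structure coefficients."""

    x_weights: np.ndarray           # p x k, variates have unit variance
    y_weights: np.ndarray           # q x k
    canonical_correlations: np.ndarray  # k, non-increasing
    x_variates: np.ndarray          # n x k
    y_variates: np.ndarray          # n x k
    x_loadings: np.ndarray          # p x k structure coefficients
    y_loadings: np.ndarray          # q x k
    reg: float
    k: int
    x_mean_: np.ndarray = field(repr=False, default=None)
    y_mean_: np.ndarray = field(repr=False, default=None)
    x_names: tuple = None
    y_names: tuple = None


def _inv_sqrt_psd(S: np.ndarray, label: str) -> np.ndarray:
    w, V = linalg.eigh(S)
    if w.min() < 1e-12 * max(w.max(), 1.0):
        raise np.linalg.LinAlgError(
            f"{label} block covariance is (near-)singular; increase reg"
        )
    return (V / np.sqrt(w)) @ V.T


def _column_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between paired columns of two centered matrices."""
    num = np.einsum("ij,ij->j", A, B)
    den = np.sqrt(np.einsum("ij,ij->j", A, A) * np.einsum("ij,ij->j", B, B))
    if (den == 0).any():
        raise ValueError("zero-variance variate")
    return num / den


def _fit_core(Xc: np.ndarray, Yc: np.ndarray, k: int, reg: float):
    """Fit on centered blocks; returns (a, b, corrs) with unit-variance
    variate scaling, correlation-ordered components, before sign fixing."""
    n, p = Xc.shape
    q = Yc.shape[1]
    Sxx = (Xc.T @ Xc) / (n - 1) + reg * np.eye(p)
    Syy = (Yc.T @ Yc) / (n - 1) + reg * np.eye(q)
    Sxy = (Xc.T @ Yc) / (n - 1)
    Wx = _inv_sqrt_psd(Sxx, "X")
    Wy = _inv_sqrt_psd(Syy, "Y")
    U, _, Vt = linalg.svd(Wx @ Sxy @ Wy, full_matrices=False)
    a = Wx @ U[:, :k]
    b = Wy @ Vt[:k].T
    a = a / (Xc @ a).std(axis=0, ddof=1)
    b = b / (Yc @ b).std(axis=0, ddof=1)
    corrs = _column_corr(Xc @ a, Yc @ b)
    order = np.argsort(-corrs, kind="stable")
    return a[:, order], b[:, order], corrs[order]


def fit_rcca(X, Y, k: int, reg: float, x_names=None, y_names=None) -> RCCAModel:
    """Fit regularized CCA on row-aligned blocks.

    ``k`` must not exceed the rank of either block; ``reg >= 0`` (with 0
    requiring full-rank blocks). Deterministic up to the documented sign
    convention.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with the same number of rows")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in input blocks")
    if reg < 0:
        raise ValueError("reg must be nonnegative")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    max_k = min(np.linalg.matrix_rank(Xc), np.linalg.matrix_rank(Yc))
    if not (1 <= k <= max_k):
        raise ValueError(f"k={k} exceeds the rank of the blocks (max {max_k})")
    a, b, corrs = _fit_core(Xc, Yc, k, reg)
    xv, yv = Xc @ a, Yc @ b
    xl, yl = compute_loadings(Xc, xv, Yc, yv)
    # Sign convention: largest-|x-loading| variable positive per component.
    flip = np.sign(xl[np.abs(xl).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    a, b, xv, yv, xl, yl = a * flip, b * flip, xv * flip, yv * flip, xl * flip, yl * flip
    return RCCAModel(
        x_weights=a, y_weights=b, canonical_correlations=corrs,
        x_variates=xv, y_variates=yv, x_loadings=xl, y_loadings=yl,
        reg=reg, k=k, x_mean_=x_mean, y_mean_=y_mean,
        x_names=tuple(x_names) if x_names else None,
        y_names=tuple(y_names) if y_names else None,
    )


def compute_loadings(X, x_variates, Y, y_variates):
    """Structure coefficients: Pearson r of each original column with its
    block's canonical variates. Returns (p x k, q x k)."""
    def block(M, V):
        M = np.asarray(M, float) - np.asarray(M, float).mean(axis=0)
        V = np.asarray(V, float) - np.asarray(V, float).mean(axis=0)
        vn = np.sqrt(np.einsum("ij,ij->j", V, V))
        mn = np.sqrt(np.einsum("ij,ij->j", M, M))
        if (vn == 0).any():
            raise ValueError("zero-variance variate")
        if (mn == 0).any():
            raise ValueError("zero-variance variable")
        return (M.T @ V) / np.outer(mn, vn)

    return block(X, x_variates), block(Y, y_variates)


def project(model: RCCAModel, Xnew, Ynew):
    """Apply the stored weights (after centering with the training means) to
    new, identically preprocessed data; no refitting."""
    Xnew = np.asarray(Xnew, dtype=float)
    Ynew = np.asarray(Ynew, dtype=float)
    if Xnew.shape[1] != model.x_weights.shape[0]:
        raise ValueError(
            f"X column mismatch: got {Xnew.shape[1]}, model expects {model.x_weights.shape[0]}"
        )
    if Ynew.shape[1] != model.y_weights.shape[0]:
        raise ValueError(
            f"Y column mismatch: got {Ynew.shape[1]}, model expects {model.y_weights.shape[0]}"
        )
    return (Xnew - model.x_mean_) @ model.x_weights, (Ynew - model.y_mean_) @ model.y_weights


@dataclass
class GridSearchResult:
    best_k: int
    best_reg: float
    cv_table: pd.DataFrame
    selection_metric: str


def _holdout_score(model: RCCAModel, Xte, Yte, metric: str) -> float:
    xv, yv = project(model, Xte, Yte)
    xv = xv - xv.mean(axis=0)
    yv = yv - yv.mean(axis=0)
    num = np.einsum("ij,ij->j", xv, yv)
    den = np.sqrt(np.einsum("ij,ij->j", xv, xv) * np.einsum("ij,ij->j", yv, yv))
    r = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    if metric == "first_component_corr":
        return float(r[0])
    if metric == "sum_holdout_corr":
        return float(r.sum())
    return float(r.mean())


def grid_search_cv(X, Y, config: RCCAConfig | None = None) -> GridSearchResult:
    """Tenfold (by default) cross-validated selection of (k, reg).

    Folds are shuffled contiguous blocks, deterministic given
    ``config.seed``. Each grid cell is scored by the held-out variate
    correlation aggregated per ``config.selection_metric`` and averaged over
    folds; ties break toward the smallest reg, then the smallest k.
    """
    config = config or RCCAConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 2 * config.cv_folds:
        raise ValueError("need at least 2 rows per fold")
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    splits = list(kf.split(X))
    rows = []
    for k, reg in product(config.n_components_grid, config.reg_grid):
        scores = []
        for tr, te in splits:
            model = fit_rcca(X[tr], Y[tr], k=k, reg=reg)
            scores.append(_holdout_score(model, X[te], Y[te], config.selection_metric))
        rows.append({"k": k, "reg": reg, "score": float(np.mean(scores)),
                     "score_sd": float(np.std(scores, ddof=1))})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["score", "reg", "k"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    return GridSearchResult(best_k=int(best["k"]), best_reg=float(best["reg"]),
                            cv_table=table, selection_metric=config.selection_metric)
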