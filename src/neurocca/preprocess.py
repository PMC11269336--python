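"""Standardization, confound residualization and multicollinearity screening.

The canonical-correlation pipeline consumes a pair of row-aligned blocks:
X = 8 cerebellar regional volumes + ICV, Y = the cognitive subscales
(optionally augmented by the CBCL total). Both blocks are Z-scored,
residualized on the confound design (intercept, age, sex, site dummies)
and re-Z-scored; ICV is treated as an anatomical variable, not a confound
regressor. Canonical correlations are invariant to the order of the
scaling steps; re-standardizing the residuals makes structure coefficients
comparable across variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ANATOMICAL_COLUMNS, COGNITIVE_COLUMNS

__all__ = [
    "ResidualizedBlocks",
    "zscore_columns",
    "residualize",
    "compute_vif",
    "pairwise_screen",
    "effect_size_label",
    "build_confound_design",
    "make_blocks",
]

#: Pearson-r magnitude bins for correlation effect sizes.
_R_BINS = ((0.5, "large"), (0.3, "moderate"), (0.1, "small"), (0.0, "negligible"))


@dataclass
class ResidualizedBlocks:
    """Paired standardized, confound-residualized matrices plus the design."""

    X: np.ndarray                 # n x 9
    Y: np.ndarray                 # n x q (4, or 5 with CBCL)
    confound_design: np.ndarray   # n x c, first column = intercept
    x_names: tuple[str, ...]
    y_names: tuple[str, ...]
    confound_names: tuple[str, ...]


def _as_2d(M, name="M") -> np.ndarray:
    arr = np.asarray(M, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got ndim={arr.ndim}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def zscore_columns(M, names=None) -> np.ndarray:
    """Z-score every column (mean 0, SD 1; SD uses the n-1 denominator).

    Raises ``ValueError`` naming the column if any column is constant.
    """
    arr = _as_2d(M)
    sd = arr.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        labels = [names[j] if names is not None else f"column {j}" for j in bad]
        raise ValueError(f"cannot Z-score constant column(s): {labels}")
    return (arr - arr.mean(axis=0)) / sd


def _collinear_columns(C: np.ndarray, names) -> list:
    """Identify columns made redundant by earlier ones (rank-revealing QR)."""
    _, R = np.linalg.qr(C)
    diag = np.abs(np.diag(R))
    tol = C.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    redundant = np.flatnonzero(diag < tol)
    return [names[j] if names is not None else int(j) for j in redundant]


def residualize(M, confounds, confound_names=None) -> np.ndarray:
    """Replace each column of ``M`` by its least-squares residual against the
    confound design (which must include an intercept column and be full
    column rank)."""
    arr = _as_2d(M)
    C = _as_2d(confounds, "confounds")
    if arr.shape[0] != C.shape[0]:
        raise ValueError("M and confounds must have the same number of rows")
    if arr.shape[0] <= C.shape[1]:
        raise ValueError("need more rows than confound columns")
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError(
            "confound design is rank deficient; collinear columns: "
            f"{_collinear_columns(C, confound_names)}"
        )
    coef, *_ = np.linalg.lstsq(C, arr, rcond=None)
    return arr - C @ coef


def compute_vif(M, names=None) -> pd.DataFrame:
    """Variance inflation factors.

    ``VIF_j = 1 / (1 - R^2_j)`` with ``R^2_j`` from regressing column j on
    all remaining columns (no intercept is added, so on centered input this
    is the usual centered VIF and orthonormal designs give exactly 1).
    Perfectly collinear columns are reported as ``inf`` and flagged, not
    raised. Columns with ``VIF > 5`` carry ``flagged=True``.
    """
    arr = _as_2d(M)
    n, p = arr.shape
    if n <= p:
        raise ValueError("need more rows than columns for VIF")
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column(s) present; VIF undefined")
    vifs = np.empty(p)
    for j in range(p):
        others = np.delete(arr, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
        resid = arr[:, j] - others @ coef
        ss_tot = float(arr[:, j] @ arr[:, j])
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        if abs(r2) < 1e-12:        # below numerical noise: orthogonal design
            r2 = 0.0
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    idx = list(names) if names is not None else list(range(p))
    return pd.DataFrame({"vif": vifs, "flagged": vifs > 5.0}, index=idx)


def effect_size_label(r: float) -> str:
    """Label a Pearson correlation magnitude: |r| >= 0.1 small, >= 0.3
    moderate, >= 0.5 large (below 0.1: negligible)."""
    mag = abs(float(r))
    for cut, label in _R_BINS:
        if mag >= cut:
            return label
    return "negligible"


def pairwise_screen(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pearson correlations among the cognitive subscales and the CBCL total,
    with magnitude labels; long-form, one row per unordered pair."""
    cols = list(columns) if columns is not None else list(COGNITIVE_COLUMNS) + ["cbcl_total"]
    data = table[cols].to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise ValueError("pairwise screen needs at least 3 rows")
    R = np.corrcoef(data, rowvar=False)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rows.append({"var_a": cols[i], "var_b": cols[j],
                         "r": R[i, j], "label": effect_size_label(R[i, j])})
    return pd.DataFrame(rows)


def build_confound_design(table: pd.DataFrame,
                          site_reference: str = "RU") -> tuple[np.ndarray, tuple[str, ...]]:
    """Confound design matrix: intercept, age, male indicator and dummy
    columns for every non-reference scan site (reference defaults to the
    largest site)."""
    sites = sorted(table["site"].unique())
    if site_reference not in sites:
        site_reference = sites[0]
    cols = [np.ones(len(table)), table["age"].to_numpy(dtype=float),
            (table["sex"].to_numpy() == "M").astype(float)]
    names = ["intercept", "age", "sex_male"]
    for s in sites:
        if s == site_reference:
            continue
        cols.append((table["site"].to_numpy() == s).astype(float))
        names.append(f"site_{s.lower()}")
    return np.column_stack(cols), tuple(names)


def make_blocks(table: pd.DataFrame, include_cbcl: bool = False,
                anatomical_columns=None, cognitive_columns=None,
                site_reference: str = "RU") -> ResidualizedBlocks:
    """Z-score, residualize on the confound design, re-Z-score; returns the
    row-aligned X/Y blocks ready for canonical correlation analysis."""
    x_names = tuple(anatomical_columns) if anatomical_columns else ANATOMICAL_COLUMNS
    y_names = tuple(cognitive_columns) if cognitive_columns else COGNITIVE_COLUMNS
    if include_cbcl and "cbcl_total" not in y_names:
        y_names = y_names + ("cbcl_total",)
    design, confound_names = build_confound_design(table, site_reference)

    def prep(cols):
        Z = zscore_columns(table[list(cols)].to_numpy(dtype=float), names=cols)
        return zscore_columns(residualize(Z, design, confound_names), names=cols)

    return ResidualizedBlocks(
        X=prep(x_names), Y=prep(y_names), confound_design=design,
        x_names=x_names, y_names=y_names, confound_names=confound_names,
    )
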