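"""Psychopathology-stratified, covariate-adjusted standardized mean differences.

Subjects are stratified by the CBCL total t-score at the established
normative cut-offs (<= 64 non-clinical, 65-69 borderline, >= 70 clinical);
cerebellar volumes are residualized on age, sex, scan site and ICV in a
single model pooled across strata (pooling preserves the between-group
mean differences of interest), and classic Cohen's d — mean difference
over the two compared groups' pooled SD — is computed per region and
stratum pair with an approximate-variance 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import build_confound_design, residualize
from .simulate import VOLUME_COLUMNS

__all__ = ["STRATA", "stratify_cbcl", "adjusted_cohens_d", "cohens_d",
           "StratifiedEffects", "stratified_effects_from_table"]

logger = logging.getLogger(__name__)

#: Stratum labels in severity order.
STRATA = ("non-clinical", "borderline", "clinical")


def stratify_cbcl(scores) -> pd.Series:
    """Map CBCL total t-scores to severity strata.

    Cut-offs assume integer t-scores; non-integer scores in the open gaps
    (64, 65) and (69, 70) are assigned to the nearer category by half-up
    rounding before classification.
    """
    s = pd.Series(scores, dtype=float)
    if s.empty:
        return pd.Series([], dtype="object")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("CBCL scores must be finite")
    rounded = np.floor(s.to_numpy() + 0.5)
    labels = np.where(rounded <= 64, STRATA[0], np.where(rounded <= 69, STRATA[1], STRATA[2]))
    return pd.Series(labels, index=s.index, dtype="object")


def cohens_d(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Classic two-group Cohen's d with an approximate-variance 95% CI.

    ``d = (mean(a) - mean(b)) / s_pooled`` with the two-group pooled SD;
    ``Var(d) ~= (na+nb)/(na*nb) + d^2 / (2*(na+nb-2))`` (large-sample normal
    approximation). Returns ``(d, ci_low, ci_high)``.
    """
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("pooled SD is zero")
    d = (a.mean() - b.mean()) / pooled
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb - 2)))
    return float(d), float(d - 1.96 * se), float(d + 1.96 * se)


@dataclass
class StratifiedEffects:
    """Long-form effect-size table plus the stratum counts."""

    table: pd.DataFrame   # region, group_a, group_b, n_a, n_b, d, ci_low, ci_high
    counts: dict
    skipped: list


def adjusted_cohens_d(volumes, labels, covariates, region_names=None) -> StratifiedEffects:
    """Covariate-adjusted Cohen's d of regional volumes across stratum pairs.

    ``volumes`` is n x r; ``covariates`` the n x c adjustment design
    (intercept, age, sex, site dummies, ICV), full rank; residualization is
    pooled across strata. Pairs where either group has n < 2 are skipped
    with a logged reason.
    """
    V = np.asarray(volumes, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    labels = pd.Series(labels).to_numpy()
    if len(labels) != V.shape[0]:
        raise ValueError("labels and volumes must have the same length")
    resid = residualize(V, covariates)
    names = list(region_names) if region_names is not None else [
        f"region_{j}" for j in range(V.shape[1])
    ]
    present = [s for s in STRATA if (labels == s).any()]
    counts = {s: int((labels == s).sum()) for s in present}
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty strata")
    rows, skipped = [], []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            ga, gb = present[i], present[j]
            ma, mb = labels == ga, labels == gb
            if ma.sum() < 2 or mb.sum() < 2:
                reason = f"pair ({ga}, {gb}) skipped: group n < 2"
                logger.info(reason)
                skipped.append(reason)
                continue
            for r, name in enumerate(names):
                d, lo, hi = cohens_d(resid[ma, r], resid[mb, r])
                rows.append({"region": name, "group_a": ga, "group_b": gb,
                             "n_a": int(ma.sum()), "n_b": int(mb.sum()),
                             "d": d, "ci_low": lo, "ci_high": hi})
    return StratifiedEffects(table=pd.DataFrame(rows), counts=counts, skipped=skipped)


def stratified_effects_from_table(table: pd.DataFrame) -> StratifiedEffects:
    """Convenience wrapper on a full cohort table: stratify by ``cbcl_total``
    and adjust the 8 regional volumes for age, sex, site and ICV."""
    labels = stratify_cbcl(table["cbcl_total"])
    design, names = build_confound_design(table)
    design = np.column_stack([design, table["icv"].to_numpy(dtype=float)])
    return adjusted_cohens_d(
        table[list(VOLUME_COLUMNS)].to_numpy(dtype=float), labels, design,
        region_names=VOLUME_COLUMNS,
    )
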