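"""Synthetic cohort generation with planted cross-block latent structure.

Generates subject-level tables shaped like a pediatric neuroimaging
phenotype file: demographics (age, sex, scan site), intracranial volume,
eight cerebellar lobular gray-matter volumes, four NIH Toolbox cognition
subscale scores, and a CBCL total t-score.

The generative model is a canonical-pair construction. Per latent ``j`` a
bivariate standard-normal factor pair ``(f_j, g_j)`` with correlation
``latent_corrs[j]`` is shared between the anatomical (X, 9 variables) and
cognitive (Y, 4 variables) blocks. On the standardized scale

    x = U f + (I - U U^T) e,      y = V g + (I - V V^T) e'

with ``U`` (9 x J) and ``V`` (4 x J) orthonormal loading-direction
matrices and isotropic standard-normal noise ``e``. Every standardized
variable then has unit variance and the *population* canonical
correlations between the blocks equal ``latent_corrs`` exactly, which is
what makes the generator usable as ground truth for recovery, power and
coverage experiments. Confound contamination (age, sex, site, and a
global "ICV driver" size factor) is added on centered codes, after which
each variable is affinely rescaled so its population mean and SD hit the
configured marginal targets exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSpec",
    "CohortSpecError",
    "VOLUME_COLUMNS",
    "ANATOMICAL_COLUMNS",
    "COGNITIVE_COLUMNS",
    "PHENOTYPE_COLUMNS",
    "COHORT_COLUMNS",
    "CONFOUND_ROW_LABELS",
    "hbn_like_spec",
    "generate_cohort",
    "generate_null_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Cerebellar regional gray-matter volume columns, fixed order.
VOLUME_COLUMNS = (
    "vol_i_v",      # anterior lobe, lobules I-V
    "vol_vi",       # lobule VI
    "vol_crus_i",   # crus I
    "vol_crus_ii",  # crus II
    "vol_viib",     # lobule VIIB
    "vol_viiia",    # lobule VIIIA
    "vol_ix",       # lobule IX
    "vol_x",        # lobule X
)

#: Anatomical block: the 8 regional volumes plus ICV as a 9th variable.
ANATOMICAL_COLUMNS = VOLUME_COLUMNS + ("icv",)

#: Cognitive block: NIH Toolbox subscale standardized scores.
COGNITIVE_COLUMNS = ("nih_list", "nih_card", "nih_flanker", "nih_processing")

#: All 14 calibrated phenotype/volumetry variables, fixed order.
PHENOTYPE_COLUMNS = ANATOMICAL_COLUMNS + COGNITIVE_COLUMNS + ("cbcl_total",)

#: Full cohort table column order.
COHORT_COLUMNS = ("subject_id", "age", "sex", "site") + PHENOTYPE_COLUMNS

#: Rows of ``confound_betas``: centered age code, male indicator, two site
#: dummies (reference = RU, the largest site) and the latent size factor.
CONFOUND_ROW_LABELS = ("age", "sex", "site_cbic", "site_si", "icv_driver")

SITES = ("CBIC", "RU", "SI")

# Cohort-level marginal targets. ICV, the NIH subscales and the CBCL total
# use the published cohort summary values; the per-lobule volume means/SDs
# are this package's own realistic calibration (cm^3).
_DEFAULT_MEANS = {
    "vol_i_v": 12.9, "vol_vi": 14.2, "vol_crus_i": 21.3, "vol_crus_ii": 14.6,
    "vol_viib": 8.2, "vol_viiia": 9.7, "vol_ix": 5.6, "vol_x": 1.15,
    "icv": 1410.59,
    "nih_list": 97.13, "nih_card": 93.46, "nih_flanker": 88.61,
    "nih_processing": 94.59,
    "cbcl_total": 57.54,
}
_DEFAULT_SDS = {
    "vol_i_v": 1.7, "vol_vi": 1.9, "vol_crus_i": 2.8, "vol_crus_ii": 2.1,
    "vol_viib": 1.3, "vol_viiia": 1.5, "vol_ix": 0.9, "vol_x": 0.18,
    "icv": 136.57,
    "nih_list": 14.69, "nih_card": 15.49, "nih_flanker": 14.01,
    "nih_processing": 23.56,
    "cbcl_total": 11.38,
}


class CohortSpecError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``x_loadvecs``/``y_loadvecs`` are (n_latents x 9) and (n_latents x 4)
    arrays of unit-norm, mutually orthogonal direction vectors;
    ``confound_betas`` is a (5 x 14) array of standardized effects of the
    codes in :data:`CONFOUND_ROW_LABELS` on each phenotype variable (in
    :data:`PHENOTYPE_COLUMNS` order).
    """

    n_subjects: int = 662
    age_range: tuple[float, float] = (5.82, 17.74)
    age_mean: float = 10.5
    age_sd: float = 2.91
    sex_ratio: float = 385 / 662          # fraction male
    site_probs: tuple[float, float, float] = (285 / 662, 315 / 662, 62 / 662)
    marginal_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    marginal_sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    n_latents: int = 0
    latent_corrs: tuple[float, ...] = ()
    x_loadvecs: np.ndarray | None = None
    y_loadvecs: np.ndarray | None = None
    confound_betas: np.ndarray | None = None
    cbcl_cognition_r: float = 0.0         # optional CBCL <-> first cognitive factor coupling
    volume_floor_frac: float = 0.01       # positivity floor, fraction of each volume mean
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_subjects, (int, np.integer)) and self.n_subjects > 0):
            raise CohortSpecError("n_subjects must be a positive integer")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise CohortSpecError("sex_ratio must lie in [0, 1]")
        probs = np.asarray(self.site_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any():
            raise CohortSpecError("site_probs must be 3 nonnegative fractions")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise CohortSpecError("site_probs must sum to 1 within 1e-12")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise CohortSpecError("age_range must be an increasing positive interval")
        for name in PHENOTYPE_COLUMNS:
            if name not in self.marginal_means:
                raise CohortSpecError(f"marginal_means missing entry for {name!r}")
            if name not in self.marginal_sds:
                raise CohortSpecError(f"marginal_sds missing entry for {name!r}")
            if not self.marginal_sds[name] > 0:
                raise CohortSpecError(f"marginal_sds[{name!r}] must be positive")
        if self.n_latents < 0:
            raise CohortSpecError("n_latents must be >= 0")
        corrs = np.asarray(self.latent_corrs, dtype=float)
        if corrs.shape != (self.n_latents,):
            raise CohortSpecError("latent_corrs length must equal n_latents")
        if ((corrs < 0) | (corrs >= 1)).any():
            raise CohortSpecError("latent_corrs must lie in [0, 1)")
        if self.n_latents > 0:
            for attr, width in (("x_loadvecs", 9), ("y_loadvecs", 4)):
                mat = getattr(self, attr)
                if mat is None:
                    raise CohortSpecError(f"{attr} required when n_latents > 0")
                mat = np.asarray(mat, dtype=float)
                if mat.shape != (self.n_latents, width):
                    raise CohortSpecError(
                        f"{attr} must have shape ({self.n_latents}, {width}), got {mat.shape}"
                    )
                gram = mat @ mat.T
                if np.abs(np.diag(gram) - 1.0).max() > 1e-10:
                    raise CohortSpecError(f"{attr} rows must be unit-norm within 1e-10")
                off = gram - np.diag(np.diag(gram))
                if np.abs(off).max() > 1e-8:
                    raise CohortSpecError(
                        f"{attr} rows must be mutually orthogonal (needed for exact "
                        "planted canonical correlations)"
                    )
        if self.confound_betas is not None:
            betas = np.asarray(self.confound_betas, dtype=float)
            if betas.shape != (5, 14):
                raise CohortSpecError(
                    f"confound_betas must have shape (5, 14) "
                    f"({len(CONFOUND_ROW_LABELS)} codes x {len(PHENOTYPE_COLUMNS)} variables), "
                    f"got {betas.shape}"
                )
        if not (-1.0 < self.cbcl_cognition_r < 1.0):
            raise CohortSpecError("cbcl_cognition_r must lie in (-1, 1)")

    def to_dict(self) -> dict:
        """JSON-serializable representation (arrays as nested lists)."""
        out = dataclasses.asdict(self)
        for key in ("x_loadvecs", "y_loadvecs", "confound_betas"):
            if out[key] is not None:
                out[key] = np.asarray(out[key]).tolist()
        out["latent_corrs"] = list(out["latent_corrs"])
        return out


def _default_loadvecs() -> tuple[np.ndarray, np.ndarray]:
    """Two planted direction pairs emulating the reported loading topography.

    Component 1 weights crus II and lobule X; component 2 weights crus I and
    lobule VI. Both are orthogonalized against the default ICV-driver
    contamination direction so the planted canonical correlations survive
    residualization exactly (ICV-driver variance is the one confound source
    that is deliberately NOT in the residualization design).
    """
    x1 = np.array([0.1, 0.15, 0.1, 0.65, 0.2, 0.2, 0.15, 0.6, 0.0])
    x2 = np.array([0.1, 0.6, 0.65, -0.2, 0.15, 0.1, 0.1, -0.25, 0.0])
    size = _default_confound_betas()[4, :9]          # ICV-driver direction in X
    basis = []
    for v in (size / np.linalg.norm(size), x1, x2):
        for b in basis:
            v = v - (b @ v) * b
        v = v / np.linalg.norm(v)
        basis.append(v)
    x_load = np.vstack(basis[1:])
    y1 = np.array([0.5, 0.75, 0.05, 0.43])           # list, card, flanker, processing
    y1 /= np.linalg.norm(y1)
    y2 = np.array([0.55, -0.1, -0.75, 0.1])
    y2 -= (y1 @ y2) * y1
    y2 /= np.linalg.norm(y2)
    return x_load, np.vstack([y1, y2])


def _default_confound_betas() -> np.ndarray:
    """Moderate standardized confound effects: growth, sex and scanner-site
    mean shifts on the volumetric variables, a shared size factor loading on
    ICV and all lobules, and no confound effects on the age-normed cognitive
    scores."""
    betas = np.zeros((5, 14))
    betas[0, :9] = 0.30     # age -> volumes + ICV
    betas[1, :8] = 0.20     # sex -> regional volumes
    betas[1, 8] = 0.50      # sex -> ICV
    betas[2, :9] = 0.15     # site CBIC shift
    betas[3, :9] = -0.20    # site SI shift (1.5T scanner)
    betas[4, :8] = 0.35     # size factor -> regional volumes
    betas[4, 8] = 0.80      # size factor -> ICV
    return betas


def hbn_like_spec(
    n_subjects: int = 662,
    latent_corrs: tuple[float, ...] = (),
    seed: int = 0,
    confounds: bool = True,
    **overrides,
) -> CohortSpec:
    """Cohort spec calibrated to the published cohort summary table.

    ``latent_corrs`` plants up to two cross-block canonical correlations
    along the default direction pairs; pass custom ``x_loadvecs`` /
    ``y_loadvecs`` via ``overrides`` for more.
    """
    n_latents = len(latent_corrs)
    kwargs = dict(
        n_subjects=n_subjects,
        n_latents=n_latents,
        latent_corrs=tuple(latent_corrs),
        confound_betas=_default_confound_betas() if confounds else np.zeros((5, 14)),
        seed=seed,
    )
    if n_latents > 0 and "x_loadvecs" not in overrides:
        if n_latents > 2:
            raise CohortSpecError(
                "default direction pairs cover n_latents <= 2; pass x_loadvecs/y_loadvecs"
            )
        xl, yl = _default_loadvecs()
        kwargs["x_loadvecs"] = xl[:n_latents]
        kwargs["y_loadvecs"] = yl[:n_latents]
    kwargs.update(overrides)
    spec = CohortSpec(**kwargs)
    spec.validate()
    return spec


def _confound_code_covariance(spec: CohortSpec) -> np.ndarray:
    """Population covariance of the 5 centered confound codes."""
    p_m = spec.sex_ratio
    p_cbic, _, p_si = spec.site_probs
    cov = np.zeros((5, 5))
    cov[0, 0] = 1.0                       # age code is standardized
    cov[1, 1] = p_m * (1 - p_m)
    cov[2, 2] = p_cbic * (1 - p_cbic)
    cov[3, 3] = p_si * (1 - p_si)
    cov[2, 3] = cov[3, 2] = -p_cbic * p_si
    cov[4, 4] = 1.0                       # ICV driver is standard normal
    return cov


def _truncnorm_params(spec: CohortSpec):
    lo, hi = spec.age_range
    a = (lo - spec.age_mean) / spec.age_sd
    b = (hi - spec.age_mean) / spec.age_sd
    return a, b, spec.age_mean, spec.age_sd


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from ``spec``; deterministic given ``spec.seed``.

    Returns a DataFrame with columns :data:`COHORT_COLUMNS`, one row per
    subject, no missing values, and ``df.attrs['seed']`` recording the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    a, b, loc, scale = _truncnorm_params(spec)
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    age_mu, age_var = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
    sex = (rng.random(n) < spec.sex_ratio).astype(int)          # 1 = male
    site = rng.choice(len(SITES), size=n, p=np.asarray(spec.site_probs, float))

    # Centered confound codes (population centering -> exact target means).
    p_cbic, _, p_si = spec.site_probs
    codes = np.column_stack([
        (age - float(age_mu)) / np.sqrt(float(age_var)),
        sex - spec.sex_ratio,
        (site == 0).astype(float) - p_cbic,
        (site == 2).astype(float) - p_si,
        rng.standard_normal(n),                                  # ICV driver
    ])

    # Latent canonical-pair structure on the standardized scale.
    J = spec.n_latents
    x_std = rng.standard_normal((n, 9))
    y_std = rng.standard_normal((n, 4))
    g1 = None
    if J > 0:
        U = np.asarray(spec.x_loadvecs, float).T                 # 9 x J
        V = np.asarray(spec.y_loadvecs, float).T                 # 4 x J
        rho = np.asarray(spec.latent_corrs, float)
        f = rng.standard_normal((n, J))
        g = rho * f + np.sqrt(1.0 - rho**2) * rng.standard_normal((n, J))
        x_std = x_std - (x_std @ U) @ U.T + f @ U.T
        y_std = y_std - (y_std @ V) @ V.T + g @ V.T
        g1 = g[:, 0]

    c = spec.cbcl_cognition_r
    cbcl_std = rng.standard_normal(n)
    if g1 is not None and c != 0.0:
        cbcl_std = c * g1 + np.sqrt(1.0 - c**2) * cbcl_std

    raw = np.column_stack([x_std, y_std, cbcl_std])              # n x 14, unit variance
    betas = (np.asarray(spec.confound_betas, float)
             if spec.confound_betas is not None else np.zeros((5, 14)))
    raw = raw + codes @ betas

    conf_var = np.einsum("ij,ik,kj->j", betas, _confound_code_covariance(spec), betas)
    means = np.array([spec.marginal_means[k] for k in PHENOTYPE_COLUMNS])
    sds = np.array([spec.marginal_sds[k] for k in PHENOTYPE_COLUMNS])
    values = means + sds * raw / np.sqrt(1.0 + conf_var)

    # Positivity floor for the volumetric variables; generation is invalid if
    # the floor is hit more than 0.1% of the time.
    vol_idx = np.arange(9)
    floors = spec.volume_floor_frac * means[vol_idx]
    below = values[:, vol_idx] < floors
    if below.mean() > 1e-3:
        raise CohortSpecError(
            f"volume positivity floor hit for {below.mean():.2%} of draws "
            "(> 0.1%); marginal means/SDs imply non-physical volumes"
        )
    values[:, vol_idx] = np.maximum(values[:, vol_idx], floors)

    df = pd.DataFrame({
        "subject_id": [f"sub-{i:05d}" for i in range(n)],
        "age": age,
        "sex": np.where(sex == 1, "M", "F"),
        "site": np.asarray(SITES)[site],
    })
    for j, name in enumerate(PHENOTYPE_COLUMNS):
        df[name] = values[:, j]
    df = df[list(COHORT_COLUMNS)]
    df.attrs["seed"] = spec.seed
    df.attrs["n_truncated"] = int(below.sum())
    return df


def generate_null_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Same as :func:`generate_cohort` with every planted correlation forced
    to zero: the two blocks are independent given the confounds."""
    null_spec = dataclasses.replace(
        spec, latent_corrs=tuple(0.0 for _ in range(spec.n_latents))
    )
    return generate_cohort(null_spec)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write the cohort table as CSV plus a ``<path>.meta.json`` sidecar
    recording the seed."""
    df.to_csv(path, index=False)
    meta = {"seed": df.attrs.get("seed"), "n_subjects": int(len(df)),
            "columns": list(df.columns)}
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return df[list(COHORT_COLUMNS)]
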