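# Methods

`neurocca` implements a multivariate brain–behavior association workflow
for a pediatric phenotype table: eight cerebellar lobular gray-matter
volumes plus intracranial volume (ICV) on one side, four NIH Toolbox
cognition subscale scores on the other, with age, sex and scan site as
confounds and the CBCL total t-score as a psychopathology severity
measure. This note records the models, the numerical choices, and what
the validation experiments do and do not establish.

## Regularized canonical correlation analysis

Canonical correlation analysis (CCA) finds weight vectors `a`, `b`
maximizing `corr(Xa, Yb)`; successive components repeat the problem in
the orthogonal complement. With a linear kernel and p = 9, q = 4 ≪ n, the
kernel formulation reduces to feature space: we shrink each block
covariance, `C_xx = S_xx + reg·I` (likewise `C_yy`), and take the SVD of
the whitened cross-covariance `C_xx^{-1/2} S_xy C_yy^{-1/2}`. Because both
blocks are Z-scored (unit diagonal covariance), `reg` acts on the
correlation scale, which makes the conventional grid
`{1e-4, 1e-2, 1, 100}` interpretable: `1e-4` is numerically classical
CCA, `100` is essentially cross-covariance (PLS-like) direction finding.

Conventions, all load-bearing for reproducibility:

- **Reported correlations** are the realized Pearson correlations between
  paired variates, not the singular values; the two coincide as
  `reg → 0`. Components are ordered by decreasing realized correlation.
- **Variate scaling**: weights are normalized so every variate has unit
  sample variance.
- **Sign**: each component is flipped so its largest-|loading| anatomical
  variable loads positively. Bootstrap alignment relies on this.
- **Loadings** (structure coefficients) are Pearson correlations between
  each original variable and its block's variate — the per-variable
  effect sizes reported by the pipeline.
- **Degenerate input**: a (near-)singular block covariance at `reg = 0`
  raises rather than silently pseudo-inverting.

### Hyperparameter selection

Tenfold cross-validation over `k ∈ {2, 3, 4}` × `reg ∈ {1e-4, 1e-2, 1,
100}` (both grids configurable). Folds are shuffled contiguous blocks,
deterministic given the seed. Each cell is scored by the correlation
between held-out X- and Y-variates, **averaged over components** and
folds. The average (rather than the sum) is deliberate: a spurious extra
component contributes a zero-mean held-out correlation, so a sum makes
model-order selection a coin flip between k and k+1, while the mean
penalizes dilution and recovers the planted component count reliably.
Sum and first-component-only metrics are available via
`RCCAConfig.selection_metric`. Ties break toward smaller `reg`, then
smaller `k` (parsimony).

## Preprocessing

Variables are Z-scored (SD denominator n−1), residualized on the
confound design (intercept, age, male indicator, site dummies with the
largest site as reference), and the residuals re-standardized. CCA is
invariant to per-column affine rescaling, so the ordering of scaling
steps does not affect correlations (tested); re-standardizing residuals
makes loadings comparable across variables. ICV is an anatomical variable
(9th column of X), not a confound regressor.

VIF uses no-intercept auxiliary regressions (`R²` uncentered). On
centered input this equals the usual centered VIF and gives exactly 1 on
orthogonal designs; `R²` below 1e-12 is treated as exactly 0 and above
1 − 1e-12 as perfect collinearity (reported as `inf`, flagged, not
raised). Values above 5 are flagged as multicollinear.

## Permutation significance

Rows of Y are permuted (X fixed), the model refit at the frozen,
observed-data `(k, reg)`, and per-component canonical correlations
collected; the component threshold is the empirical 95th percentile and
`p = (#{null ≥ observed} + 1)/(n_perm + 1)` (add-one correction; the
plain proportion is recovered as `n_perm → ∞`). Because `S_xx` and
`S_yy` are invariant under row permutation of Y, the whiteners are
computed once and only the cross-covariance SVD is redone per draw —
verified to match full refits to machine precision. Hyperparameter
re-selection inside the permutation loop is not done by default (wrap the
grid search per draw for that variant).

## Bootstrap stability

Subjects are resampled with replacement and the model refit; draws
producing a constant column are redrawn (≤ 10 retries, logged). Each
bootstrap solution is aligned to the original before aggregation:
component order and sign are indeterminate under resampling, so the
concatenated (X; Y) loading matrix is matched to the reference by the
signed permutation maximizing mean per-component cosine (optimal
assignment on the |cosine| matrix); full orthogonal Procrustes is
available but signed permutation is adequate and interpretable at k = 2.
A degenerate (all-zero) bootstrap loading matrix falls back to identity
alignment and is flagged.

Intervals are reported in two forms — percentile [2.5, 97.5] (default,
safer under asymmetry) and bootstrap mean ± 1.96 SD — and a component is
"stable" when its percentile correlation interval excludes zero. The
bootstrap ratio is the original-sample loading divided by the bootstrap
SD of the aligned loadings, a pseudo-z index (|ratio| > 2 ≈ reliable).

**Known bias, documented rather than corrected:** the bootstrap
distribution of an in-sample canonical correlation is shifted upward
relative to the population value, for two stacked reasons: the observed
estimate itself is overfit (at p=9, q=4, n=662 and a true correlation of
0.5 the mean estimate is ≈ 0.518, sampling SD ≈ 0.029), and each
resample contains only ≈ 0.632·n distinct subjects, inflating refit
correlations by a further ≈ +0.014. Percentile intervals therefore
measure *sampling stability of the estimate*, not unbiased coverage of
the population correlation: in the coverage experiment
(`calibration.bootstrap_coverage`, planted r = 0.5, n = 662) the planted
value falls inside the interval in ≈ 84–87% of replicates, with every
miss from above. Stability conclusions (CI excludes zero) are
conservative under this bias; population-level effect sizes should be
read from held-out projections (`project` on a held-out half), not from
in-sample bootstrap intervals.

## Stratified effect sizes

CBCL total t-scores map to non-clinical (≤ 64), borderline (65–69) and
clinical (≥ 70) strata; non-integer scores in the open gaps are assigned
by half-up rounding (`floor(t + 0.5)`), avoiding banker's-rounding
surprises at exact halves. Volumes are residualized on age, sex, site and
ICV in a single model pooled across strata — within-stratum adjustment
would absorb the group differences under study. Cohen's d uses the two
compared groups' pooled SD, with the large-sample approximate variance
`(n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b−2))` for the 95% CI. Pairs with a
group of n < 2 are skipped with a logged reason.

## Synthetic cohort generator

The generator emulates the marginal structure of a large pediatric
neuroimaging cohort (n = 662 default): truncated-normal age (mean 10.5,
SD 2.91, range 5.8–17.7 y), 58% male, three scan sites (43/48/9%), and
fourteen phenotype variables calibrated to published cohort summary
means/SDs where available (ICV 1410.59 ± 136.57 cm³; NIH List/Card/
Flanker/Processing 97.13 ± 14.69, 93.46 ± 15.49, 88.61 ± 14.01,
94.59 ± 23.56; CBCL total 57.54 ± 11.38). Per-lobule volume means/SDs
are this package's own realistic choices (e.g., crus I 21.3 ± 2.8 cm³,
lobule X 1.15 ± 0.18 cm³), since no public per-lobule summary was
available for calibration.

Cross-block structure uses a canonical-pair construction: per latent j a
bivariate normal factor pair with correlation `latent_corrs[j]`; on the
standardized scale `x = U f + (I − UU^T) e` with orthonormal loading
directions U (and likewise for Y). Every standardized variable then has
exactly unit variance and the population canonical correlations equal the
planted values exactly — the property all recovery/power/coverage
experiments rely on. This is why the direction vectors are required to be
mutually orthogonal within a block, and why the block noise is not fully
independent across variables (independent noise would attenuate the
planted correlations by an unknown factor).

Confounds act additively on centered codes (standardized age, male
indicator, site dummies, and a latent "ICV driver" size factor loading
on ICV and all lobules); each variable is then affinely rescaled so the
population mean/SD hit the marginal targets exactly. Age/sex/site effects
vanish exactly under downstream residualization; the ICV driver is
deliberately *not* in the residualization design, so the default planted
directions are orthogonalized against it to keep the planted correlations
exact after preprocessing. Volumes are floored at 1% of their mean;
generation errors out if more than 0.1% of draws hit the floor. CBCL is
independent of cognition by default, with an optional coupling parameter
(`cbcl_cognition_r`) for sensitivity analyses.

What the generator does **not** emulate: site-specific variance or
covariance differences (mean shifts only), non-Gaussian tails, skewed or
heteroscedastic volume distributions, missing data, and segmentation
error. Passing tests therefore establish the statistical machinery's
correctness and calibration under a Gaussian, correctly-specified
confound model — not robustness of the scientific conclusions on real
cohort data.

## Problem sizes in the validation suites

The Monte-Carlo suites use 200 null cohorts × 500 permutations (type-I),
100 replicates × 500 permutations (power/recovery), 200 replicates ×
1000 bootstrap draws (coverage), 20 toy instances (oracle), 50 replicates
(effect-size recovery) and n = 10⁵ (generator calibration) — sizes at
which Monte-Carlo standard errors are small relative to the asserted
bands while a full validation run completes in minutes on one core.
Production inference defaults are 10,000 permutations and 10,000
bootstrap draws.

## CBCL-augmented variant

`run_cbcl_variant` refits with the CBCL total added to the cognitive
block, freezing `(k, reg)` at the base run's cross-validated selection so
the comparison isolates the added variable (re-selection is switchable).
The report flags conclusion changes and checks that the augmented
correlations fall inside the base model's bootstrap CIs. Note that adding
even an independent variable raises the permutation null of max-type
statistics, so a marginal component's p-value can cross 0.05 while the
correlations are unchanged — the CI comparison is the robust invariance
check.
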