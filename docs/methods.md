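# Methods

`multifun` implements the statistical chain used to relate soil
microbial diversity to ecosystem multifunctionality in large-scale soil
surveys, together with a ground-truthed synthetic landscape generator so
that every stage is testable without field data.  This note records the
models, the defaults and the numerical choices.

## Diversity metrics

The unit of observation is an OTU table (taxa × samples, non-negative
integer counts).  Before any metric is computed the table is filtered of
singletons (taxa whose total count over all samples is exactly 1) and
rarefied: each sample is subsampled without replacement to a common
depth, implemented as a multivariate hypergeometric draw.  A single
rarefaction draw is used (repeat-averaging is available via repeated
calls with different seeds); samples whose total falls below the depth
are dropped with a warning rather than padded, so all retained samples
have identical sampling effort.  Preset depths 25,113 (16S) and 23,588
(ITS) are provided as `RAREFACTION_PRESETS`.

* **Shannon diversity** H = −Σ pᵢ log₂ pᵢ over taxa with pᵢ > 0.  The
  default base is 2 so values are in bits; natural log is available via
  the `base` argument.
* **Richness** is the count of taxa with a nonzero count.
* **Faith's phylogenetic diversity** is the total branch length of the
  minimal subtree connecting a sample's observed taxa to the tree root
  (stem inclusive, the classic convention; a root edge length, when the
  newick carries one, counts toward the stem).  `include_root=False`
  restricts to branches below the observed tips' most recent common
  ancestor.  The implementation is an explicit union of tip-to-root
  paths; tests cross-check it against scikit-bio's independent
  implementation.  PD is intended for 16S-style trees; ITS alignments
  are too variable to support a reliable tree, so no fungal PD is
  computed by the pipeline.

## Averaging multifunctionality index

Six ecosystem functions are used by default: ammonium, nitrate,
potential net N mineralization, available P, DNA concentration (a soil
biomass proxy) and NDVI (plant productivity).  Site-level preparation
happens in a fixed order:

1. **Microsite aggregation** — where vegetated and bare-ground
   microsites were measured separately, site values are cover-weighted
   means, v = (c_veg·v_veg + c_bare·v_bare)/(c_veg + c_bare).
2. **Bulk-density correction** — per-mass soil functions are multiplied
   by bulk density (g cm⁻³) to a per-volume basis; NDVI is untouched.
   Multiplication is our reading of "correcting for bulk density"; the
   correction is linear, so it only matters where densities vary widely.
3. **Normalization** — a function is natural-log transformed when all
   its values are strictly positive, |sample skewness| > 1, and logging
   reduces that magnitude.  This operationalizes the usual eyeballed
   "log-transform when needed" step reproducibly; explicit per-function
   overrides ("log", "square", "none") take precedence.
4. **Z-scores** — (x − mean)/sd with the n−1 denominator, per function,
   across the sites of one data set.
5. **M** — the per-site mean of the standardized functions.  Missing
   values are complete-case per function: a site is dropped only from
   the functions where it is missing, and `n_functions_used` records how
   many entered its mean.

By construction M has site-mean 0, is invariant to positive affine
rescaling of any function, and for k mutually independent standardized
functions Var(M) → 1/k.

## Multiple-threshold multifunctionality

Each function is expressed as a fraction of its maximum, defined as the
mean of its top 5% of observations (m = ceil(0.05·n) values, so at least
one), which robustifies the denominator against a single extreme plot.
Functions with negative raw values (net N mineralization can be
negative) are shifted by their minimum first, with a logged warning —
fractions of a maximum are meaningless across a sign change.  For each
integer threshold t in 1..99, the number of functions whose fraction
strictly exceeds t/100 is counted per site ("surpassing" is read as
strict; ties do not count), and that count is regressed on diversity by
OLS.  Plain OLS is used deliberately — counts are small and bounded and
this matches the procedure the approach is known by; thresholds where
the count is constant are reported with slope 0, CI [0, 0] and a
degenerate flag rather than dropped, keeping the grid rectangular.
t = 0 is excluded by default (degenerate for strictly positive
functions) and available via `include_zero`.  The curve summary reports
the argmax-slope threshold and the contiguous threshold intervals whose
95% CI excludes zero.

## OLS and SAR regression

The diversity–multifunctionality regression is fitted twice: by OLS and
by a simultaneous-autoregressive **error** model

    y = Xβ + u,  u = λWu + ε,  ε ~ N(0, σ²I),

the standard choice in spatial ecology when residuals, not the process,
are autocorrelated (the lag form is out of scope).  W is row-standardized
k-nearest-neighbour (k = 8 by default; kNN keeps every site connected),
with great-circle distances and ties broken toward the smaller site
index.  λ is estimated by maximizing the profile log-likelihood, with
log|I − λW| evaluated from the (possibly complex) eigenvalues of W as
Σ log|1 − λeᵢ|; the optimizer is bounded Brent on the admissible
interval (1/e_min, 1) with tolerance 1e-8, and β, σ² follow by GLS at
λ̂.  At λ = 0 the concentrated likelihood equals the OLS likelihood
exactly, which tests assert.  Because no standard R² exists for SAR,
the reported pseudo-R² is the squared Pearson correlation between y and
the trend predictions Xβ̂ (recorded in the fit metadata).  Models are
compared by AICc = AIC + 2k(k+1)/(n−k−1), with k counting coefficients
plus σ² (plus λ for SAR).

## Random-forest importance

Predictor importance for multifunctionality uses regression random
forests: bagged CART trees with mtry = one third of the predictors (the
regression default).  Trees are scikit-learn CART regressors; the
bagging and all out-of-bag accounting are implemented in the package so
per-tree OOB errors are available: for each tree, the MSE of its OOB
cases is computed before and after permuting each predictor among those
cases, the increase is averaged over trees, and reported as a percentage
of the baseline OOB MSE (%IncMSE; a raw-difference mode exists).
Categorical predictors (ecosystem type) are one-hot encoded and permuted
jointly, so importance is reported per original variable.

Significance is by permutation of the **response**: the forest and its
importances are recomputed on each permuted data set, and
p = (1 + #{null ≥ observed})/(1 + B), floored at 1/(B+1).  The model
statistic is the pooled out-of-fold cross-validated R² (5 folds), which
may be negative for uninformative models.  Defaults are 5,000 trees and
5,000 permutations; calibration tests run the same machinery with small
forests, which leaves permutation p-values exactly calibrated because
the null statistic is recomputed identically.

## Path analysis

The structural models are recursive (acyclic) observed-variable path
models.  All variables are standardized after declared transforms (log,
square — declared per variable, not auto-detected), and each endogenous
variable is regressed by OLS on its parents.  For this model class with
unconstrained exogenous covariances, equation-wise OLS is the maximum-
likelihood estimator, so no general SEM optimizer is needed; the ML
discrepancy is still used for fit testing:

* implied correlation matrix Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ, with Ψ holding
  the sample covariances among exogenous variables (saturated) and the
  residual variances 1 − R² of endogenous ones;
* F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p, χ² = (n − 1)F, df = p(p+1)/2 minus
  free parameters (edges + exogenous moments + residual variances);
* RMSEA = sqrt(max(χ² − df, 0)/(df(n − 1))), reported as 0 with a
  saturation flag when df = 0.

**Composites.** Conceptually related indicators (bacterial and fungal
diversity) can enter as one composite: weights are the OLS coefficients
of the standardized anchoring target on the standardized indicators, and
the weighted sum is rescaled to unit variance.  The weights are exported;
total effects can be split over indicators in proportion to them.

**Bootstraps.** Coefficient p-values are nonparametric case-resampling
bootstraps with the two-sided percentile rule and +1 smoothing,
p = 2·min((1+#{b≤0}), (1+#{b≥0}))/(1+B); replicates that fail (rank
deficiency after resampling) are dropped and counted, with a warning
above 1%.  Overall fit is additionally confirmed by the Bollen–Stine
bootstrap: the data are rotated as Y* = Y S^(−1/2) Σ̂^(1/2) so the
fitted model holds exactly, and p is the fraction of bootstrap χ²
values at or above the observed one (undefined at df = 0).  The
composite scores are treated as observed columns inside this rotation.
Repeated refits run through a compiled numpy fast path whose agreement
with the reference implementation is pinned to machine precision by
tests.

**Total effects.** direct = B, total = (I − B)⁻¹ − I (the finite series
ΣBᵏ for acyclic B), indirect = total − direct.  When exogenous variables
are uncorrelated by design, the total effect on the outcome equals the
model-implied bivariate correlation, which tests verify by simulation.

## Synthetic landscape generator

The generator emulates the statistical structure the analyses assume,
with every coefficient returned as ground truth:

* Sites are uniform on a lon/lat rectangle (Iberian-scale, 36–44° N);
  covariates (distance from equator, altitude, MAT, MAP, soil pH) get
  dryland-plausible means and spreads (MAT 18 ± 5 °C, MAP 400 ± 150 mm,
  pH 7.8 ± 0.6, altitude 800 ± 400 m) plus spatially autocorrelated
  structure injected through the same SAR error model the regression
  module estimates — closing the loop for parameter-recovery tests.
* Latent diversity is a linear function of standardized covariates plus
  iid noise.  Default covariate signs follow the dryland pattern (MAP
  positive, pH negative); all are configurable.
* Each function is effect·diversity + covariate terms + SAR noise, then
  placed on plausible raw scales (affine placement is irrelevant to all
  standardized downstream analyses).  The default diversity effect is
  0.4 per function on the standardized scale — a moderate effect of the
  size the recovery tests target — with λ = 0.5 and unit noise.
* The OTU table draws per-site taxon abundances log-normal(0, σᵢ²),
  normalized and sampled multinomially at fixed depth, so column sums
  equal the read depth exactly.  σᵢ maps inversely (by rank) from latent
  diversity onto `evenness_range` = (0.5, 2.0): diverse sites get even
  communities, so realized Shannon diversity tracks the latent driver.
  Expected Shannon is strictly decreasing in σ (tested on a grid).
* The phylogeny is a pure-birth (Yule) tree with tips labelled to match
  the OTU table.
* Default n = 78 sites mirrors a global dryland survey's scale; one
  master seed spawns independent sub-streams per component (coordinates,
  covariates, diversity noise, functions, OTUs, tree), so changing one
  component's parameters never perturbs another's draws.

What the generator does **not** emulate: sequencing error, chimaeras and
taxonomic structure; non-Gaussian covariate distributions; measurement
error in functions; any particular empirical spatial covariance (the SAR
form is an assumption chosen for testability, not an estimate of real
field structure).  Passing tests therefore demonstrate that the
machinery is correct and calibrated, not that real soils behave like the
generator.

## Pipeline

`run_all` chains the stages — simulate/load → singleton filter →
rarefaction → diversity → averaging index → threshold curves → OLS/SAR →
RF importance → path model — writing each artifact (CSV/TSV/newick/JSON)
with a provenance header (stage, seed, package version; canonical
formats like the classic OTU TSV and newick stay unannotated, with
provenance in the run log).  Every stochastic stage derives its seed
from the manifest's master seed, so a rerun with the same manifest is
bit-identical.  The default a-priori path model sends every covariate to
diversity, climate and pH also directly to multifunctionality, and
diversity to multifunctionality; the two spatial surrogates act only
through diversity, leaving df = 2 so the fit tests are non-trivial.  The
CLI exposes each stage (`simulate`, `diversity`, `mfi`, `thresholds`,
`regress`, `rf`, `sem`, `validate`, `run-all`).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run everything at sizes a
laptop handles comfortably: landscapes of 40–120 sites (78 for the
headline reproduction), SAR recovery over 200 replicates at n = 400,
random-forest null calibration over 200 data sets × 499 permutations
with small forests (permutation p-values are exactly calibrated at any
forest size), path-model calibration over 60 replicates × 199
bootstraps, and 500 trees / 199 permutations / 499 bootstraps in the
acceptance run.  The full-scale defaults (5,000 trees, 5,000
permutations, 2,000 bootstraps) remain the API defaults for real
analyses.

## Known limitations

* The bulk-density correction formula and the per-data-set transform
  lists are package choices where the field procedures are commonly left
  unstated; both are configurable.
* The SAR pseudo-R² has no canonical definition; ours (squared
  correlation of y with Xβ̂) is recorded in fit metadata and should not
  be compared against other software's values.
* BIOM support covers the JSON (v1.0) encoding only.
* Composites are regression-weighted against a single anchoring target;
  other composite conventions exist and give different weight scales
  (the composite's unit-variance scores make downstream paths
  comparable).
* No latent-variable measurement models, non-recursive models, FIML
  missing-data handling, or Bayesian spatial models.
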