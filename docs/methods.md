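# Methods

`dimbrain` implements an analysis chain for mapping data-driven
psychopathology dimensions onto high-dimensional brain features, together
with a synthetic-cohort generator that provides ground truth for every
stage.  This note records the models, the defaults and the reasoning behind
the genuinely open design choices.

## Synthetic cohort generator

The generator emulates the statistical shape of a large multi-site
pediatric cohort rated on a 119-item behavior checklist (items scored
0/1/2), with demographic/anthropometric covariates and per-modality imaging
feature tables.

**Latent dimensions.** `k = 3` latent dimensions are drawn through a
Gaussian copula.  Two regimes are packaged as presets:

* `ica_regime_config()` — statistically independent dimensions with
  standardized-exponential marginals.  Non-Gaussian marginals are required
  for a linear ICA to be identifiable; a skewed, heavy-tailed distribution
  is also a reasonable cartoon of symptom-burden scores.
* `efa_regime_config()` — pairwise latent correlation 0.6 with Gaussian
  marginals, matching the latent-response model that polychoric correlation
  assumes.

For non-normal marginals the configured `latent_corr` is the copula
(normal-score) correlation; the realized Pearson correlation is mildly
attenuated.  Recovery tests therefore score estimates against the realized
sample correlation of the generated scores, which is the estimand actually
present in the data (at n = 2000 the latent draws alone can move a 0.6
correlation by ±0.04).

**Hierarchical items.** Each dimension is composed of `n_sub = 3`
sub-syndromes correlated 0.8 with their parent (innovations share the
parent's marginal family); every item loads on one sub-syndrome of its
owning dimension, with main weights U(0.5, 0.9), small secondary loadings
U(−0.05, 0.05), and 9 pure-noise items.  The hierarchy mirrors how broad
problem dimensions decompose into narrower syndromes in real checklist
data, and it is load-bearing for model-order selection: without narrower
structure inside each dimension, an overfactored ICA has nothing to split
and its solutions do not destabilize, so no stability criterion could
prefer the true order.  The secondary loadings are kept small because an
oblique rotation's factor-correlation estimate is attenuated by random
cross-loadings (see the geomin notes below).

The EFA preset disables the sub-syndrome split (`n_sub = 1`): it emulates
the broad 3-factor level of the hierarchy.  With the split enabled, Horn's
parallel analysis correctly retains the nine sub-syndromes instead — a
coherent finer-grained solution, but not the level this pipeline targets.

**Ordinal ratings.** Item propensity = (latent weights · scores) + N(0, 1),
cut at two strictly increasing per-item thresholds (base cuts near 0 and 1,
jittered), giving category frequencies of roughly 50/35/15 percent — skewed
toward 0 the way problem items are, while keeping every cell populated for
polychoric estimation.

**Covariates and sites.** Sex, age (9–11 y), race, handedness, scanner
(a site property), weight, height, pubertal stage and in-scanner head
motion; 22 balanced sites by default, with an optional per-site mean shift
of the continuous covariates.

**Imaging features.** Per modality, 60 features; each planted feature is a
weighted latent score (or its standardized centered square when flagged
nonlinear) plus covariate confounding (age + sex everywhere, motion for the
diffusion- and resting-state-like modalities) plus unit Gaussian noise;
null features carry only confounds and noise.

What the generator does *not* emulate: real item wording or real marginal
distributions (many real items are >90 % zero), realistic spatial
covariance among imaging features, site-by-loading interactions,
missing-data mechanisms beyond MCAR, and family structure.  Passing
recovery tests therefore show the estimators work under the assumed
data-generating model, not that the scientific conclusions transfer to any
particular real cohort.

## ICA with stability-based model-order selection

Ratings are treated as numeric 0/1/2, centered, and whitened by SVD.  At
model order k, fixed-point ICA (logcosh contrast, symmetric decorrelation,
tol 1e−5, max 500 iterations; sklearn's FastICA engine on the pre-whitened
top-k principal directions) is refit over many randomized runs.  **Each run
perturbs both the random start and the sample**, refitting on a random
half-sample.  Pure random restarts on the full data are available
(`run_frac=1.0`) but are nearly deterministic on strongly structured data:
at k = k_true + 1, for example, the extra component is the orthocomplement
of the true sources inside the top-(k+1) whitened subspace and is therefore
perfectly reproducible, so a restart-only index is structurally unable to
penalize overfactoring.  Sample perturbation restores the intended signal:
underfactored solutions flip which mixture survives, overfactored solutions
split dimensions differently on each half-sample.

Components are matched across runs to the first run's components by greedy
one-to-one assignment on absolute loading correlation; per-component
stability is the mean matched |r| and the overall index its mean across
components.  The selected order maximizes overall stability (ties to the
smaller model).  Consensus loadings are the sign-aligned average of matched
run loadings; consensus scores are the least-squares projection of the
centered ratings onto them, symmetrically decorrelated, so score columns
are exactly uncorrelated in-sample.  Components are oriented so each
column's largest-magnitude loading is positive.

Leave-one-site-out stability refits the consensus with each site excluded
and reports the mean matched |loading r| against the full-sample solution
per site; sites under 10 subjects are skipped with a warning.

## Polychoric EFA with geomin rotation

**Polychoric correlation** uses the two-step estimator: thresholds from
inverse-normal cumulative marginal proportions, then the correlation
maximizing the contingency-table likelihood whose cells are bivariate
normal rectangle masses, by bounded scalar search over (−0.999, 0.999)
(xatol 1e−6).  Rectangle masses are evaluated in closed form through
Owen's T function — exact to machine precision against the generic
multivariate-normal CDF, and fast enough for all 7021 pairs of 119 items in
seconds.  Zero-margin categories are collapsed with a warning; a raw matrix
with negative eigenvalues is smoothed by eigenvalue clipping at 1e−6 and
diagonal rescaling.

**Factor count** comes from Horn's parallel analysis: observed eigenvalues
against the 95th percentile of eigenvalues from 100 Pearson correlation
matrices of standard-normal data of the same shape (a column-permutation
null that preserves the ordinal marginals is available behind a flag).

**Extraction.** `run_efa` extracts by principal-axis factoring (iterated
communalities initialized at squared multiple correlations, tol 1e−7).
Plain component extraction (eigenvectors scaled by root eigenvalues) is
provided as `extract_pca_loadings` and as an option, but it spreads unique
item variance into the loadings, and at 110 items this measurably
attenuates the rotated factor correlation (≈ −0.06 at the population
level); since the pipeline's factor solution is a common-factor model, PAF
is the default.

**Geomin rotation** minimizes Σ_i (Π_j (λ_ij² + ε))^{1/m} over oblique
rotations by gradient projection with monotone backtracking, from 30 random
orthonormal starts (first start = identity), keeping the lowest criterion.
ε follows the conventional per-m schedule (1e−4 for m = 2, 1e−3 for m = 3,
1e−2 for m ≥ 4); larger ε over-smooths the criterion and attenuates the
recovered factor correlations.  Even at the population level, geomin with
ε > 0 and random small cross-loadings recovers a 0.6 factor correlation as
≈ 0.55 — an intrinsic property of the criterion, not an optimization
failure (the gradient-projection minimum matches a 0.1° brute-force sweep
to ~1e−6 at m = 2).

**Factor scores** use the regression (Thurstone) method,
W = R⁻¹ Λ Φ, applied to standardized numeric items and re-standardized.
When R is near-singular (the near-deterministic-item limit, or heavy
smoothing) the inverse is ridge-regularized with a warning; without this
the weights amplify polychoric estimation noise catastrophically.  Note a
hard information ceiling: 3-category items cap score–truth correlation
around 0.96 regardless of method.

## Kernel-regularized least squares (KRLS)

Predictors and outcome are standardized; K_ij = exp(−‖x_i − x_j‖²/σ²) with
σ² = D (the number of predictor columns); c = (K + λI)⁻¹y via one
eigendecomposition, reused across the λ search.  λ minimizes the sum of
squared leave-one-out errors by the closed-form identity e_i = c_i /
[(K+λI)⁻¹]_ii, with Brent search on log λ in (1e−3, 1e3), auto-expanded
(×100, up to three times) when the minimizer lands on a bound.

Pointwise effects: analytic kernel derivatives for continuous predictors;
for binary predictors (auto-detected two-valued columns, e.g. one-hot
covariates with reference level dropped) the fitted first difference
between raw levels 1 and 0, computed by updating the cached squared
distances in the changed coordinate only.  The average marginal effect
(AME) is the sample mean of the pointwise effect.  Every pointwise effect
is linear in c (effect = M c), so Var(AME) = n⁻² vᵀ V(c) v with v the
column sums of M and V(c) = σ̂²(K+λI)⁻²; σ̂² is the residual sum of squares
over n − tr(K(K+λI)⁻¹) (effective residual degrees of freedom).  p-values
use the standard-normal reference; simulation at n = 300 puts the null
rejection rate at ≈ 5.3 %.  The estimator is isolated in one function so an
alternative variance could be swapped in.

Each fit is O(n³); samples above a configurable cap (default 2500) are
reduced to a seeded random subset.

## Association mapping

One KRLS model per (dimension, modality): the dimension score is the
outcome and all of the modality's features are entered jointly together
with the adjustment covariates (sex, age, race, handedness, scanner,
weight, height, pubertal stage; motion added for diffusion- and
resting-state-like modalities; total intracranial volume never).  The
feature t-values of the full-data model form the dimension's association
profile; covariate rows stay in the AME table but out of the profile.
Benjamini–Hochberg FDR is applied within each model over feature p-values
only.

Stability: 100 seeded half-samples drawn without replacement, the model
refit from scratch on each (λ re-selected), BH applied within each rerun;
a feature's signed count is the number of significant reruns times the
sign of its full-data effect.  Dimension scores are held fixed across
reruns — the decompositions are not refit inside the resampling loop
(a switchable choice; refitting would mix decomposition variability into
what is meant to be a sample-composition check).  Profiles are compared by
Spearman correlation of t-value vectors regardless of significance.

A caution established while validating the null contract: a feature that
is marginally null but shares a confound with truly predictive features
has a *genuine* nonzero partial association in a joint model (it helps
subtract the confound), so false-positive control is only meaningfully
assessed on all-null feature blocks.

The validation direction (an external outcome regressed on all dimension
scores entered together) reuses the same machinery with roles swapped
(`fit_association_model`).

## Problem sizes

Defaults are desk-scale: n = 2000 subjects, 119 items, 3 dimensions,
22 sites, 60 features per modality; the model-order sweep uses 100
randomized runs per candidate order, stability maps 100 half-sample
reruns, and calibration checks 500 replicates of n = 300.  All stages are
seeded and bit-reproducible; `scripts/acceptance.py` reruns the whole
chain at these sizes in a few minutes on one CPU.

## Known limitations

* The stability index is one member of a family (cluster-quality variants
  differ in how they penalize between-component similarity); it is pinned
  by tests rather than claimed canonical.
* Geomin's factor-correlation attenuation under cross-loadings means
  recovered Φ is a mild underestimate by construction.
* KRLS inference ignores the variability of the selected λ and of the
  bandwidth convention; calibration is verified by simulation, not theory.
* Ordinal 0/1/2 items cap every score-recovery correlation near 0.96.
* The generator's nulls are exactly null; real "null" features correlated
  with signal features through unmodeled confounds will show genuine
  partial associations, as the joint-model caution above explains.
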