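# dimbrain

Data-driven psychopathology dimensions and their brain correlates.

`dimbrain` is a Python library for a question that recurs in population
neuroscience: when child-behavior ratings are decomposed into latent
dimensions, do *statistically independent* dimensions (ICA) map onto more
dissociable brain correlates than *correlated* dimensions (oblique factor
analysis)?  The package implements both decomposition routes for ordinal
item ratings, a kernel-based association engine for relating each dimension
to high-dimensional imaging feature tables, and a resampling layer that
scores how robust every association is.  A seeded synthetic-cohort
generator with planted ground truth makes the entire chain testable without
access to restricted cohort data.  It is aimed at methodologists and
psychiatric-neuroimaging researchers who want the machinery, not the
(access-restricted) data.

## What it computes

* **ICA with stability-based model-order selection.**  Ordinal items
  (0/1/2, treated numerically and whitened) are decomposed by fixed-point
  ICA (logcosh contrast).  For each candidate order k ∈ {2,…,10} the fit is
  repeated over randomized runs (random half-sample + random start);
  components are matched across runs by absolute loading correlation and
  the order with the most reproducible components wins.  Robustness across
  acquisition sites is quantified by leave-one-site-out refits.
* **Polychoric EFA with geomin rotation.**  The items' polychoric
  correlation matrix (two-step estimator; bivariate-normal rectangle masses
  through Owen's T) feeds Horn's parallel analysis, principal-axis
  extraction and an oblique geomin rotation, yielding correlated factors
  Λ, Φ and regression-method factor scores.
* **KRLS association models.**  Each dimension score y is regressed on one
  modality's features plus covariates with Gaussian-kernel regularized
  least squares, ŷ = Kc, c = (K+λI)⁻¹y, λ by closed-form leave-one-out CV.
  Each predictor's **average marginal effect** — the sample mean of
  ∂ŷ/∂x_d (or the 0→1 first difference for binary predictors) — acts as a
  coefficient analogue with SE, t and p, while the surface itself is free
  to be nonlinear.
* **Stability maps and profile comparison.**  Every model is rerun on 100
  random half-samples; a feature's signed count is (number of reruns
  FDR-significant at q ≤ 0.05) × sign of the full-data effect, an integer
  in [−100, 100].  Dimensions are compared by Spearman correlation of their
  feature t-value profiles.

## Worked example

`examples/02_ica_model_order.py` generates a 2000-subject cohort with three
planted independent dimensions and runs the model-order sweep:

```
stability by component count:
  k=2: 0.735 #############################
  k=3: 0.979 #######################################
  k=4: 0.850 ##################################
  k=5: 0.705 ############################
  k=6: 0.677 ###########################
selected k = 3 (overall stability 0.979)
loading recovery |r| vs ground truth: [0.984 0.992 0.988]
```

The curve peaks at the true dimension count: underfactored solutions flip
which source mixture survives and overfactored solutions split dimensions
differently on each half-sample, so only k = 3 reproduces run after run.
The recovered item loadings correlate > 0.98 with the planted ones.

`examples/06_ica_vs_efa_profiles.py` shows the central contrast on a cohort
whose latent dimensions truly correlate (0.6):

```
ICA: between-dimension profile Spearman rho = [ 0.06 -0.14 -0.21] (mean -0.10)
EFA: between-dimension profile Spearman rho = [0.41 0.48 0.42] (mean +0.43)
```

Oblique factors inherit the latent correlation, so their brain-association
profiles overlap; the independence-forced ICA dimensions map onto
dissociable profiles.  The other examples cover cohort simulation, the
polychoric EFA pipeline, KRLS marginal effects (including a quadratic
effect invisible to Pearson correlation), and stability maps.

A thin CLI wraps the same stages for shell use:

```bash
dimbrain run-all --seed 1 --out runs/demo       # simulate → ica → efa → associate
dimbrain validate runs/demo/cohort              # schema/alignment checks
```

## Layout

```
src/dimbrain/
  synthetic.py   seeded cohort generator with ground truth
  ica.py         whitening, fixed-point ICA, stability, model order, LOSO
  efa.py         polychoric matrix, parallel analysis, geomin, factor scores
  krls.py        kernel ridge, LOO lambda, marginal effects + inference
  mapping.py     association models, BH-FDR, stability maps, profile similarity
  pipeline.py    run configuration, orchestration, manifest, table validation
  cli.py         thin command-line wrapper
docs/methods.md  models, defaults, numerical choices, limitations
examples/        one narrative script per capability
```
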