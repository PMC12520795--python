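# Methods

This note documents the statistical machinery in `invasdm`: the models and
procedures, their assumptions, the parameters that matter, what the
synthetic landscapes emulate (and deliberately do not), and the numerical
choices made where the design was genuinely open.

## Occurrence preparation

Raw occurrence tables carry coordinates, a coordinate-uncertainty radius
(CU, meters), a date, a provenance class and a region label. Preparation
runs in a fixed order:

1. **Validity/terrestrial clean** — drop records with non-finite
   coordinates, records outside the grid, and records in cells where every
   predictor layer is no-data (water or unmapped area).
2. **Region-specific CU filter** — a record survives iff CU ≤ the region's
   threshold (strictly greater is excluded; a CU exactly at the threshold
   survives). Defaults: 1 km in the densely GPS-sampled invasive range,
   15 km in the native range, where many records are retrospectively
   georeferenced museum specimens. Records with *missing* CU are excluded by
   default with a logged count: the thresholds are defined on CU, and
   silently keeping unmeasured records would leak imprecise locations. This
   is configurable (`keep_missing_cu`).
3. **Per-cell thinning** — at most one presence per grid cell; the retained
   representative is the first record in input order, which is deterministic
   and does not depend on possibly-missing dates.

Cell assignment is `floor((coord − origin)/cell_size)` with half-open cell
intervals, so boundary points belong to exactly one cell.

## Sampling-effort surface

Effort absorbs observer bias. Each cell receives the natural log of its
observation count, with `0` for unsampled cells and `0.33` for
single-observation cells so that minimal effort is separated from no effort
(ln 1 would collapse them). The layer enters every model fit as a covariate,
is never centered or scaled (the log transform already constrains its
range), and its mean non-zero value is stored: at projection time every cell
is set to that constant, producing maps of environmental suitability with
observer bias held fixed. The constant is always computed from the training
effort layer, never hard-coded.

## Predictor stack

Pairwise Pearson correlations are computed over cells where all compared
layers have data, pooled across regions (a single model spans both ranges,
so a single standardization is the consistent choice). Layers are pruned
greedily until no pair exceeds |r| = 0.7: at each step, among layers in a
still-violating pair, the one with the largest mean |r| against the other
kept layers is dropped (ties broken alphabetically). The threshold is the
only part of this rule fixed by convention; the greedy order is a
deterministic, standard choice. Remaining layers are centered and scaled to
mean 0 / sd 1 over non-NA cells; the constants are frozen on the modeling
extent and reused at projection, preventing leakage between fit and
projection domains. The effort layer is exempt from both pruning and
standardization.

## Pseudo-absences

Background points are drawn at a 1:1 ratio with presences per region,
uniformly without replacement within a set, in ten independently seeded sets
(set *k* uses `base_seed + k`); a cell may recur across sets. Two exclusion
geometries reflect record precision:

* **Cell exclusion** (precise records): only cells containing a presence are
  ineligible; neighbors remain viable.
* **Buffer exclusion** (imprecise records): a cell is ineligible iff its
  rectangle intersects any disc of radius CU centered on a record. The test
  is exact — clamp the disc center into the rectangle and compare the
  distance to the radius (closed inequality, so tangent cells are excluded)
  — with no polygon discretization. The candidate window around each disc is
  widened by one cell because a closed rectangle tangent at exactly the
  radius can sit just outside the half-open bounding cells.

Both modes also require non-NA predictors at eligible cells. Mode is
configured per region (invasive → cell, native → buffer by default).

## Fitting design

Each pseudo-absence set joined with the presences gives a balanced model
frame. Frames are split 70/30, stratified by region × class, in ten repeated
seeded splits — repeated random splits rather than disjoint folds, which
reconciles a 70/30 partition with ten "folds" per set. The full design is
`n_algorithms × n_pa_sets × n_reps` constituent fits; every fit's seed
derives deterministically from (algorithm, pa_set, rep).

The registry ships Random Forest (500 trees, √p features per split),
Gradient Boosting (1000 stages, depth 3, learning rate 0.01), a
cost-complexity-pruned classification tree (pruning strength chosen by
internal stratified CV), a single-hidden-layer neural network (8 units,
weight decay 0.01), XGBoost, and a penalized-logistic Maximum-Entropy
approximation (background-contrasted logistic regression; fidelity to the
original MaxEnt software is a non-goal). All defaults are overridable per
algorithm, and unknown keys pass through to the underlying estimator.
Class weights are deliberately omitted: prevalence is held at 0.5 by the 1:1
design. Flexible discriminant analysis and MARS are defined as optional
plugin slots but not implemented (no suitable backing library is declared as
a dependency).

## Evaluation

* **TSS** is maximized over candidate thresholds = midpoints of consecutive
  sorted unique scores plus {0, 1}; positive classification uses
  `score ≥ threshold` and ties in the maximum break toward the larger
  threshold. This matches a brute-force scan over all distinct scores.
* **Continuous Boyce index**: 101 overlapping windows of width 0.1 × the
  combined score range slide across it; each window's P/E is the presence
  fraction over the background fraction inside it; the index is the Spearman
  correlation of P/E with the window midpoint. Windows with zero background
  mass are skipped; duplicate consecutive P/E values are retained (rank
  averaging handles ties); a completely flat P/E curve returns 0 (presences
  track background exactly). Window width and count are configurable. Note
  the index is exactly invariant under positive *affine* score transforms
  (windows scale with the range) but not under general monotone transforms,
  which warp window membership.
* Metrics are always reported per region; pooled numbers never substitute
  for per-region ones, because the two ranges differ enormously in sample
  size.
* Ensemble candidates are evaluated per split (predict on each split's
  validation rows) and averaged across splits; a split whose background
  scores collapse to a single value has an undefined Boyce and is skipped in
  the average rather than aborting the run.
* The final model maximizes `mean(TSS_A, TSS_B, BI_A, BI_B)`; whether one
  averages regions or metrics first is immaterial for an unweighted mean of
  four numbers. Ties break by mean TSS, then lexicographic id.

## Ensembles

EMmean is the unweighted mean of member probabilities; EMca is the mean of
member votes at each member's own TSS-optimal threshold (outputs on the
lattice k/m); EMwmean weights members by TSS with negative values floored to
zero — a model with no skill should not drag the ensemble; the cutoff is
configurable. Members are combined by a streaming running sum, so maps of
hundreds of members never materialize simultaneously; the result equals the
eager computation to float precision.

## Importance and regional inference

Permutation importance of a predictor is `1 − r` between reference
predictions and predictions after shuffling that predictor's column,
averaged over nine seeded shuffles (Pearson r, per the convention of the
ensemble-SDM tooling this follows). A constant shuffled prediction vector is
assigned r = 1 (no measurable effect); a constant *reference* vector makes
all importances 0, flagged. Raw importances (range [0, 2]) are scaled to sum
to one within each run × region over **all model covariates, effort
included** — effort is a model predictor like any other, and under
effort-biased sampling it legitimately carries much of the
presence/background discrimination. Region-wise importance uses the
validation partition of the first pseudo-absence set.

Regional differences are modeled with a beta-regression mixed model fitted
by maximum likelihood with a Laplace approximation over run-level random
intercepts:

* logit mean and log precision both follow `region * predictor`
  (cell-means coding, which makes estimated marginal means read directly off
  the coefficients);
* scaled importances of exactly 0 or 1 are legal outcomes but outside the
  beta support, so all outcomes are squeezed by `y' = (y(n−1) + 0.5)/n`
  before fitting (the perturbation vanishes with n and is flagged);
* the inner mode search is a vectorized per-group Newton iteration with
  analytic first and second derivatives; the outer optimization is L-BFGS-B
  with tight tolerances; the parameter covariance is the inverse of a
  central-difference observed-information matrix;
* with fewer than 5 runs the random-intercept variance is not identifiable
  and the model falls back to fixed effects only.

Contrasts are `EMM(native) − EMM(invasive)` on the logit scale with
delta-method standard errors, so **negative ⇒ more influential in the
invasive range**; p-values are two-sided normal, with optional Holm
adjustment (off by default; raw p-values are the primary report). On
identical data this inference reproduces `glmmTMB` + `emmeans` output to
four decimal places (estimates, SEs, z, p).

A calibration caveat: with three predictors and fifty runs, a perfectly
calibrated Wald z satisfies |z| < 2 about 94–95% of the time per contrast,
so the event "all contrasts below 2" occurs in only ~85% of replicates.
Calibration checks in the test suite therefore assess the pooled
per-contrast coverage.

## Projection, independent validation, overlap

Projection evaluates the selected ensemble over the standardized stack with
effort either observed or standardized (every cell set to the stored mean
non-zero training effort). NA propagates. Independent survey points are
aggregated to one labeled point per cell with precedence to presences, then
scored against the standardized-effort map. Focal-species overlap thins each
species' occurrences to one per cell and reports the mean ± SE
(sd/√n, ddof = 1) of map suitability at those cells; occurrences in NA cells
are dropped with a logged count, and extraction is cell-level only (no
buffer averaging).

## Synthetic landscapes

The generator produces what the analysis assumes and nothing more:

* **Predictors** are Gaussian white noise smoothed with a Gaussian kernel
  (sigma = smoothing radius in cells, default 3), standardized per layer.
  Correlated pairs are made by mixing pre-smoothing noise
  (`L2 = ρL1 + √(1−ρ²)N`); a shared kernel preserves ρ exactly in
  expectation, giving analytic control of the realized correlation.
* **Truth** is a logistic suitability surface over named layers.
* **Occurrences** are drawn per cell with probability ∝ suitability ×
  effort within a region — records never fall in zero-effort cells —
  with coordinates at the cell center plus uniform within-cell jitter, and
  CU drawn from a region preset: log-normal with median 31 m (clipped to
  1–1000 m) for the invasive range; a 50/50 mixture of Uniform(4 m, 1 km)
  and Uniform(1 km, 15 km) for the native range, mirroring a roughly even
  split between sub-kilometer and heavy-tailed georeferencing precision.
* **Observer activity** is its own smooth field; effort observations
  cluster on it via an exponential tilt.

Not emulated: real climate structure, anisotropy, temporal sampling
dynamics, detection covariates other than effort, non-planar coordinate
systems. Passing tests on these landscapes shows the *machinery* is correct
under the stated assumptions (proportional detection, logistic truth,
stationary smooth fields); it does not validate those assumptions for any
real dataset.

The proportionality of sampling to suitability × effort is an assumption of
the synthetic module, chosen as the simplest detection model consistent with
effort-biased community science data.

## Demo configuration and problem sizes

The bundled demo (`invasdm/data/demo.yaml`) runs a 60 × 60 km landscape,
6 predictors with one pair at r = 0.85, ~800/120 raw occurrences, 3
pseudo-absence sets × 2 reps × {RF, CTA}. Because the demo's native strip is
only ~21 km wide, its heavy CU tail is scaled to 5 km
(`sampling.native_cu_tail_max_m`); with the full 15-km tail, uncertainty
buffers would cover every native cell and pseudo-absence generation would
(correctly) refuse to run. The 15-km mixture remains the package-default
preset for landscape extents that can support it. Test and acceptance
studies use 40–120-cell grids, 150-tree forests and 2–10 pseudo-absence
sets — sizes at which every measured property (correlation contracts,
importance ranking, contrast calibration) is stable across seeds.

## Known limitations

* Buffer exclusion is exact for discs on a planar grid; geographic
  (lon/lat) coordinates are out of scope.
* The beta GLMM supports a single scalar random intercept (run); crossed or
  nested random effects are not implemented.
* Raster alignment/resampling is a precondition, not an operation: synthetic
  stacks are born aligned, and heterogeneous real rasters must be aligned
  upstream.
* External raster I/O uses the plain-text ESRI ASCII grid format; TIFF
  output would need a raster I/O dependency.
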