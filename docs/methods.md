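# Methods

This note documents the models implemented in `habsel`, the synthetic
study conditions, and the numerical and design choices a maintainer or
reviewer would want spelled out.  Everything stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted beyond
what the code reproduces.

## 1. Synthetic landscape

Covariates live on a square planar grid (default 30-m cells, origin at the
lower-left corner, no CRS: the analysis needs only relative geometry).

* **Land-cover masks** (forest, shrub, development, agriculture, forestry
  activity) are thresholded smooth Gaussian random fields; the threshold
  is the empirical quantile matching the requested cover fraction, so the
  realised occupancy equals the target up to sampling noise of the field.
  Forestry activity is a single time-invariant mask.
* **Riparian network**: the low-|value| band of a smooth field blended
  with elevation, giving a branching valley-bottom pattern; **roads** are
  rasterised sinusoidal polylines crossing the grid.
* **Derived layers.**  Focal percent cover uses a circular window by
  cell-centre inclusion (ties at exactly the radius included), clipped at
  the grid boundary with the denominator reduced accordingly.  Forest
  *edge density* is boundary length per window area (m/m²): every
  forest/non-forest 4-neighbour adjacency contributes one cell width,
  split half to each adjacent cell before window summation.  This is a
  standard landscape-ecology convention, stated explicitly because edge
  metrics are not standardised across tools.  Distances are Euclidean
  cell-centre transforms; an *empty* mask yields a grid-diagonal sentinel
  with a warning so that configurations omitting a land-use class remain
  well-defined.  Slope is a central-difference gradient on a
  reflect-padded grid; ruggedness the 3×3 SD; TPI the cell minus the mean
  of its 8 neighbours.
* **Standardisation.**  `standardize_stack` z-scores every continuous
  layer over study pixels.  All generative truth coefficients and all
  fitted coefficients are therefore per-SD effect sizes, directly
  comparable across covariates.  Binary masks are kept raw, and class
  summaries are reported on the raw (percent) stack for interpretability.

## 2. Generative agents — the study conditions

`TruthParams` fixes the conditions under which every downstream guarantee
is tested:

| parameter | default | meaning |
|---|---|---|
| gamma shape, scale | 2.0, 300 m | step-length kernel (mean 600 m, matching a large carnivore at 2-h fixes) |
| von Mises κ | 0.5 | mild forward persistence of turning angles |
| fix interval | 2 h | collar schedule |
| β_move | +1 forest edge density, −1 development cover@150 | per-SD selection while moving |
| β_feed | +2 forest cover@500, −1 development cover@500 | per-SD selection while feeding |
| conflict (intercept, a_feed, b_move) | (−6, +1, −1) | logistic incident thinning on SD-rescaled surfaces |

**Movement.**  Each step proposes C = 200 candidate endpoints from the
kernel (first turn uniform; turns thereafter measured from the previous
bearing) and selects one with probability ∝ exp(β_move·x) at the endpoint;
candidates leaving the extent are redrawn.  Choosing among C kernel draws
converges to the continuous exp-tilted kernel only as C grows; measurement
showed ~5% coefficient attenuation at C = 50, several SEs at cohort scale,
while C = 200 leaves no measurable bias — hence the default.

**Kills** are rejection-sampled inside the animal's MCP with density
∝ exp(β_feed·x) against the cellwise maximum weight; a wild/domestic label
(P(wild) = 0.977) is attached for bookkeeping only.  **Incidents** thin
uniform proposals by sigmoid(intercept + a_feed·feed + b_move·move) on the
SD-rescaled surfaces.  The baseline −6 places the process in the
rare-event regime in which incident density is ∝ exp(linear predictor) —
the regime the incident-vs-background GLM itself presumes; at higher
baselines the case-control fit estimates an attenuated linear
approximation of log-sigmoid rather than the generative slopes.

**What the generator does not emulate:** temporal autocorrelation beyond
the step kernel, collar error, habitat-driven fix loss, home-range
territoriality, prey dynamics, and reporting bias in incidents.  Passing
recovery tests therefore demonstrate estimator correctness under the
model's own assumptions, not robustness to these real-data features.

## 3. Movement iSSA

* 20-m minimum step filter.  Sub-threshold fixes are *re-threaded* by
  default (the next step starts at the last retained fix), keeping turning
  angles defined along the retained chain; plain deletion (which breaks
  the chain) is available behind a flag.  The first step of a chain has no
  defined turn: its stratum's available turns are drawn uniform and its
  `cos_ta` column is set to a stratum-constant 0, which cancels exactly in
  the conditional likelihood.
* The gamma/von Mises kernel is fitted to the pooled retained used steps
  of the model dataset (not per individual); the von Mises mean direction
  is fixed at 0 and κ is capped at 100 (degenerate collinear tracks), with
  a warning.
* Available endpoints outside the raster are redrawn up to 100 times,
  after which the stratum is dropped and counted — preserving the exact
  1 used + J available regularity the likelihood code assumes.
* Terrain covariates (slope, ruggedness, TPI) are averaged over the
  Bresenham cell traversal of each step; distances and percent cover are
  read at the end cell at the chosen scale.
* **Estimation.**  Damped Newton ascent from β = 0 with analytic gradient
  and observed information, gradient-norm tolerance 1e−8, max 500
  iterations; SEs from the inverse observed information.  Separation is
  diagnosed explicitly (a covariate ranking used above available in every
  stratum also sends the gradient to zero at infinite β, so large-|β|
  "converged" fits are re-flagged).  The Poisson tier profiles the
  per-stratum intercepts in closed form (α_s = −logsumexp of the stratum's
  linear predictors); its slopes and SEs coincide with the conditional fit
  and its log-likelihood differs by exactly −n_strata, both verified in
  tests.
* **Two estimation tiers** replace individual-level random slopes: the
  pooled fixed-effects fit and per-individual fits combined by inverse
  variance.  Measured at the default recovery conditions, the pooled RSF
  tier is essentially unbiased while the per-individual tier attenuates
  slopes 10–15% (small per-animal samples; inverse-variance weights
  correlate with smaller estimates), so recovery checks report the pooled
  tier.

## 4. Feeding RSF

100% MCP (convex hull of all fixes) defines availability; 10 uniform
points per kill are drawn by bounding-box rejection.  The logistic fit
uses statsmodels; on suspected separation a weakly informative ridge
(1e−4 on slopes, never the intercept) stabilises the fit and the result is
flagged.  The intercept of a pooled fit reflects the 1:10 used:available
ratio (≈ log 0.1) and shifts by −log m when availability is multiplied by
m, while slopes are stable — both tested.

## 5. Model selection and validation

* AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with n = number of strata for
  conditional fits and number of points otherwise: strata are the
  independent likelihood contributions of the conditional model.
* Scale of effect: one single-covariate model per candidate radius,
  lowest AICc wins, ties (ΔAICc < 1e−6) to the smaller radius.
* Two-stage search: stage 1 selects the best human and best nonhuman
  candidate model separately; stage 2 fits the lattice {nonhuman, human,
  union, union minus each single human term} and returns the lowest-AICc
  member (ties toward fewer parameters).  The lattice contains the stage-1
  winners, so the final AICc can never exceed theirs.
* Cross-validation is animal-blocked (all strata/points of an animal stay
  together) with k = 5 folds.  Held-out rows are scored by the habitat
  part of the linear predictor and cut into 10 *equal-count quantile*
  bins; the Spearman correlation between bin rank and the used:available
  ratio per occupied bin is reported per fold.  Quantile bins are the
  standard used:expected validation convention; equal-width bins on the
  exponential w scale leave upper bins nearly empty and were measured to
  destabilise the statistic (mean R_s 0.62 vs ~1.0 on identical strong-
  truth data), so the quantile convention is used and documented here.
* Out-of-sample surface validation assigns held-out animals' fixes to
  study-area-wide suitability quantile bins and reports the occupancy
  table; under a good surface the top bins are modal.

## 6. Mapping and conflict

`w(x) = exp(Σ β_j x_j)` per cell.  Movement adjustment terms (log SL,
cos TA) are step attributes, not landscape attributes, and are excluded
from mapping; intercepts shift all cells equally and are likewise
excluded.  Surfaces are rescaled by standardising the *linear predictor*
(not w): the transform is affine, numerically stable, and invariant to
affine changes of η.  Terciles cut at the 33.3%/66.6% empirical quantiles
(type-7 interpolation), half-open intervals with the upper class closed;
on tie-free rasters each class holds one third of the pixels to one-pixel
rounding (fitted surfaces can carry large tied atoms — e.g. zero-edge
regions — where exact thirds are impossible; the classification is still
deterministic and monotone-invariant).  The 9-class bivariate overlay
reports areas and the two conditional high-given-high shares; class
summaries draw 1000 uniform cells per class (with replacement if the
class is smaller, logged).  The conflict GLM is a binomial fit of
incidents vs a 10:1 uniform background sample on the two rescaled
surfaces, via statsmodels.

## 7. Problem sizes

Defaults were chosen so the full suite and the acceptance script each run
in minutes on one CPU while keeping every statistical check at the scale
its guarantee is stated for: recovery uses 20 replicate cohorts of 20
animals (500 steps, 50 kills each); conflict recovery 50 replicates of
500 incidents against 5000 background points; cross-validation a
30-animal cohort; classification guarantees a 300×300 raster.  Landscapes
are 128×128–160×160 cells (≈ 3.8–4.8 km squares at 30 m), large relative
to the 600-m mean step so tracks rarely pin against the boundary.

## 8. Known limitations

* Random-slope mixed models are deliberately replaced by the two fixed-
  effect tiers; heterogeneous-truth cohorts are analysed per class via
  `cohort_runner` rather than by partial pooling.
* The iSSA availability kernel is fitted from selection-tilted used steps;
  with the default spatially smooth covariates the induced bias is below
  estimation error at the tested scales, but strongly step-length-
  correlated covariates would require an additional linear step-length
  adjustment term.
* Incident thinning and the conflict GLM are mutually consistent only in
  the rare-event regime (see §2).
* Raster I/O is plain-text ESRI ASCII grid; no projection metadata.
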