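# habsel — behavior-specific habitat selection with a verifiable synthetic pipeline

`habsel` implements a complete behavior-specific habitat-selection analysis
for a large carnivore moving through a mosaic of wildland, working and
developed landscapes: an integrated step selection analysis (iSSA) of
movement, a resource selection function (RSF) of feeding (kill) sites,
habitat-suitability mapping with a bivariate tercile classification, and a
point-process GLM relating both suitability surfaces to the locations of
human–wildlife incidents.

Real GPS collar data for such analyses are typically sensitive and cannot
be shared.  `habsel` therefore pairs the full inference pipeline with a
first-class synthetic-data generator: a gridded covariate landscape and an
agent-based simulator whose selection coefficients, movement kernel and
incident-thinning coefficients are *known*.  Every stage of the analysis
can then be scored against ground truth — parameter recovery, scale-of-
effect identification, cross-validated predictive skill, classification
guarantees and conflict-coefficient recovery — which is the package's test
and acceptance surface.  It is aimed at movement ecologists and
biostatisticians who want a transparent, fully checkable reference
implementation of this model family.

## The models

**Movement (iSSA).**  A track is decomposed into 2-hour steps; steps
shorter than 20 m are removed as stationary noise.  Each used step is
matched with J = 10 available steps sharing its start point, with lengths
drawn from a gamma distribution and turning angles from a von Mises
distribution fitted to the observed steps.  Selection is estimated by the
conditional-logistic (stratum softmax) likelihood

```
l(β) = Σ_s [ β·x_used(s) − log Σ_j exp(β·x_j(s)) ],
```

with log step length and cos turning angle as movement adjustment terms.
A Poisson reformulation with one free intercept per stratum — profiled out
in closed form — reproduces the slopes exactly and is used as a
cross-check.

**Feeding (RSF).**  Kill sites are contrasted with 10 uniform points per
kill inside the animal's 100% minimum convex polygon, via logistic
regression (pooled fixed-effects tier, plus a per-individual
inverse-variance tier).

**Selection and validation.**  Percent-cover covariates enter at a
scale of effect chosen by single-covariate AICc (movement: 150 m vs 1 km;
feeding: 100 m / 500 m / 1 km); a two-stage AICc search picks the best
human and nonhuman covariate sets and then their combination lattice.
Final models are validated by animal-blocked k-fold cross-validation using
a binned Spearman rank correlation between predicted suitability and the
used:available ratio.

**Mapping and conflict.**  Fitted coefficients predict relative
suitability `w(x) = exp(β₁x₁ + … + βₙxₙ)` per 30-m cell.  Surfaces are
rescaled to SD units, cut at their 33.3%/66.6% quantiles into
low/moderate/high terciles, and overlaid into a 9-class bivariate raster.
A binomial GLM models incident (1) vs uniform background (0) points as a
function of the two rescaled surfaces.

## Worked example

```python
import habsel as hs
from habsel.pipeline import DEFAULT_TRUTH, build_movement_design

stack  = hs.generate_landscape(hs.LandscapeConfig(shape=(128, 128)), seed=1)
zstack = hs.standardize_stack(stack)          # coefficients are per-SD
tracks, _ = hs.simulate_cohort(
    zstack, {c: DEFAULT_TRUTH for c in hs.AGE_SEX_CLASSES},
    {"AF": 2, "AM": 2, "DF": 2, "DM": 2}, n_steps=250, n_kills=0, seed=2)
design = build_movement_design(
    tracks, zstack, J=10, seed=3,
    covariate_spec=[("forest_edge_density", None),
                    ("development_cover", 150)])
fit = hs.fit_conditional_logit(
    design, ["forest_edge_density", "development_cover@150",
             "log_sl", "cos_ta"])
print(fit.summary_frame().round(3))
```

prints (seeds as above):

```
                        coef     se  lower  upper
forest_edge_density    1.009  0.028  0.955  1.064
development_cover@150 -0.816  0.099 -1.010 -0.621
log_sl                 0.409  0.029  0.353  0.465
cos_ta                 0.212  0.038  0.137  0.286
```

The generative truth was +1 on forest edge density and −1 on development
cover (per SD): both estimates sit within two standard errors of truth,
and the movement adjustment terms absorb the difference between the
empirical availability kernel and the true one.  The
`examples/` directory contains one short script per capability
(landscape synthesis, cohort simulation, the two model fits, model
selection + validation, mapping + conflict), each printing its numbers
with a line on what they mean.  `habsel run-all --seed 0 --out run/`
executes the whole pipeline from a shell and writes every table, raster
(ESRI ASCII grid) and a hashed run manifest.

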