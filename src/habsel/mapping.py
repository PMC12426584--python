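"""Suitability mapping and conflict analysis.

The fitted selection coefficients are pushed back onto the covariate
stack: w(x) = exp(beta_1 x_1 + ... + beta_n x_n) per cell gives a relative
suitability surface for each behavior.  Surfaces are rescaled to SD units
(so iSSA- and RSF-derived surfaces share a common scale), classified into
low / moderate / high terciles, cross-tabulated into a 9-class bivariate
raster, and summarised by random within-class sampling.  Incident points
are contrasted with uniform background points in a binomial GLM on the two
rescaled surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import FitResult, IncidentSet
from .landscape import CovariateStack, RasterGrid
from .selection import MOVEMENT_ADJUSTMENT_TERMS, ModelSpec

TERCILE_QS = (0.333, 0.666)
CLASS_NAMES = ("low", "moderate", "high")

__all__ = ["SuitabilitySurface", "BivariateClassRaster", "predict_surface",
           "rescale_sd", "tercile_classify", "bivariate_overlap",
           "summarize_classes", "sample_background", "fit_conflict_glm"]


@dataclass
class SuitabilitySurface:
    """Predicted relative suitability for one behavior."""

    behavior: str
    eta: RasterGrid               # linear predictor
    w: RasterGrid                 # exp(eta)
    rescaled: RasterGrid | None = None   # eta in SD units over study pixels
    source: str = ""


def predict_surface(stack: CovariateStack, fit: FitResult,
                    spec: ModelSpec) -> SuitabilitySurface:
    """Evaluate w(x) = exp(sum beta_j x_j) over every cell.

    Movement adjustment terms (log step length, cosine turn) are step
    attributes, not landscape attributes, and are excluded; so is any
    intercept, which shifts all cells equally and drops out of both the
    relative surface and the SD rescaling.
    """
    ref = stack.reference
    eta = np.zeros(ref.shape)
    for name in spec.covariates:
        if name in MOVEMENT_ADJUSTMENT_TERMS or name == "intercept":
            continue
        if name not in fit.params.index:
            raise KeyError(f"fit has no coefficient for {name!r}")
        if "@" in name:
            base, radius = name.rsplit("@", 1)
            grid = stack.layer(base, int(radius))
        else:
            grid = stack.layer(name)
        eta += float(fit.params[name]) * grid.values
    return SuitabilitySurface(
        behavior=spec.behavior,
        eta=ref.like(eta, f"{spec.behavior}_eta"),
        w=ref.like(np.exp(eta), f"{spec.behavior}_w"),
        source=",".join(spec.covariates))


def rescale_sd(surface: SuitabilitySurface) -> SuitabilitySurface:
    """Standardise the linear predictor to mean 0, SD 1 over study pixels.

    Rescaling eta (not w) keeps the transform affine and numerically
    stable; any affine transform of eta yields the same rescaled layer.
    """
    v = surface.eta.values
    sd = v.std()
    if sd == 0:
        raise ValueError("surface has zero variance; cannot rescale")
    surface.rescaled = surface.eta.like((v - v.mean()) / sd,
                                        f"{surface.behavior}_rescaled")
    return surface


def tercile_classify(raster: RasterGrid) -> RasterGrid:
    """Classify cells into low (0) / moderate (1) / high (2) by the 33.3%
    and 66.6% empirical quantiles over all study pixels.

    Half-open intervals with the upper class closed; a constant raster
    collapses into a single class with a warning.  The classification is
    invariant to strictly monotone transforms of the values.
    """
    v = raster.values
    q1, q2 = np.quantile(v, TERCILE_QS)   # type-7 interpolation
    if q1 == q2:
        warnings.warn("degenerate quantiles; raster collapses to one class",
                      stacklevel=2)
    classes = np.zeros(v.shape)
    classes[v >= q1] = 1
    classes[v >= q2] = 2
    return raster.like(classes, f"{raster.name}_tercile")


@dataclass
class BivariateClassRaster:
    """9-level movement × feeding tercile cross-classification."""

    codes: RasterGrid             # 3 * move_class + feed_class
    table: pd.DataFrame           # per combination: cells, km2, pct
    conditional_shares: dict[str, float]

    @property
    def high_high_pct(self) -> float:
        row = self.table[(self.table["move_class"] == "high")
                         & (self.table["feed_class"] == "high")]
        return float(row["pct"].iloc[0])


def bivariate_overlap(move_classes: RasterGrid,
                      feed_classes: RasterGrid) -> BivariateClassRaster:
    """Overlay the two tercile rasters into 9 combinations.

    Reports cells, area (km²) and percent of study area per combination,
    plus the two conditional shares: the fraction of high-movement cells
    also classed high-feeding, and vice versa.
    """
    if move_classes.shape != feed_classes.shape \
            or move_classes.origin != feed_classes.origin \
            or move_classes.resolution != feed_classes.resolution:
        raise ValueError("class rasters are not aligned")
    m = move_classes.values.astype(int)
    f = feed_classes.values.astype(int)
    codes = 3 * m + f
    total = codes.size
    cell_km2 = (move_classes.resolution / 1000.0) ** 2
    rows = []
    for mc in range(3):
        for fc in range(3):
            n = int(np.sum(codes == 3 * mc + fc))
            rows.append(dict(move_class=CLASS_NAMES[mc],
                             feed_class=CLASS_NAMES[fc], code=3 * mc + fc,
                             cells=n, km2=n * cell_km2,
                             pct=100.0 * n / total))
    table = pd.DataFrame(rows)
    hh = int(np.sum((m == 2) & (f == 2)))
    shares = {
        "feed_high_given_move_high": 100.0 * hh / max(int(np.sum(m == 2)), 1),
        "move_high_given_feed_high": 100.0 * hh / max(int(np.sum(f == 2)), 1),
    }
    return BivariateClassRaster(move_classes.like(codes, "bivariate_class"),
                                table, shares)


def summarize_classes(biv: BivariateClassRaster, stack: CovariateStack,
                      classes: list[tuple[str, str]],
                      covariates: list[str], n_points: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Mean ± SD of covariates over random points within bivariate classes.

    For each requested (move, feeding) class, ``n_points`` cells are drawn
    uniformly (with replacement when the class holds fewer cells, logged)
    and the requested covariates are averaged.  Empty classes are skipped
    with a warning.
    """
    rng = np.random.default_rng(seed)
    codes = biv.codes.values.astype(int)
    out = []
    for mc_name, fc_name in classes:
        code = 3 * CLASS_NAMES.index(mc_name) + CLASS_NAMES.index(fc_name)
        ii, jj = np.nonzero(codes == code)
        if len(ii) == 0:
            warnings.warn(f"class {mc_name}/{fc_name} empty; skipped",
                          stacklevel=2)
            continue
        replace = len(ii) < n_points
        if replace:
            warnings.warn(f"class {mc_name}/{fc_name} has {len(ii)} cells "
                          f"< {n_points}; sampling with replacement",
                          stacklevel=2)
        sel = rng.choice(len(ii), size=n_points, replace=replace or True)
        for cov in covariates:
            if "@" in cov:
                base, radius = cov.rsplit("@", 1)
                vals = stack.layer(base, int(radius)).values[ii[sel], jj[sel]]
            else:
                vals = stack.layer(cov).values[ii[sel], jj[sel]]
            out.append(dict(move_class=mc_name, feed_class=fc_name,
                            covariate=cov, mean=float(vals.mean()),
                            sd=float(vals.std(ddof=1)), n=n_points))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# conflict GLM
# ---------------------------------------------------------------------------

def sample_background(extent: tuple[float, float, float, float], n: int,
                      seed: int = 0) -> pd.DataFrame:
    """Uniform background points over the study extent."""
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    return pd.DataFrame({"x": rng.uniform(xmin, xmax, n),
                         "y": rng.uniform(ymin, ymax, n)})


def fit_conflict_glm(incidents: IncidentSet, background: pd.DataFrame,
                     move_surface: SuitabilitySurface,
                     feed_surface: SuitabilitySurface) -> FitResult:
    """Binomial GLM of incident (1) vs background (0) points on the two
    SD-rescaled suitability surfaces.

    The linear predictor is intercept + b_feed * feed + b_move * move; 95%
    CIs follow from the reported SEs.  Quasi-separation is flagged.
    """
    for s in (move_surface, feed_surface):
        if s.rescaled is None:
            raise ValueError(f"{s.behavior} surface is not SD-rescaled")
    pts = pd.concat([
        incidents.points[["x", "y"]].assign(case=1),
        background[["x", "y"]].assign(case=0),
    ], ignore_index=True)
    feed = feed_surface.rescaled.value_at(pts["x"].to_numpy(),
                                          pts["y"].to_numpy())
    move = move_surface.rescaled.value_at(pts["x"].to_numpy(),
                                          pts["y"].to_numpy())
    X = sm.add_constant(np.column_stack([feed, move]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(pts["case"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
    idx = pd.Index(["intercept", "feed", "move"])
    res = FitResult(
        params=pd.Series(np.asarray(fit.params), index=idx),
        bse=pd.Series(np.asarray(fit.bse), index=idx),
        llf=float(fit.llf), nobs_units=len(pts),
        model_family="binomial_glm", converged=bool(fit.converged),
        vcov=pd.DataFrame(np.asarray(fit.cov_params()), index=idx,
                          columns=idx))
    if np.abs(res.params.iloc[1:]).max() > 30:
        res.diagnostics["separation_suspected"] = True
    return res
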