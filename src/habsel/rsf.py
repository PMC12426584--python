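"""Feeding-site resource selection functions (RSF).

Kill (feeding) locations are contrasted with availability sampled
uniformly inside each animal's 100% minimum convex polygon (MCP) — ten
available points per kill — and selection is estimated by logistic
regression of used (1) versus available (0) points.  Two estimation tiers
are provided: a pooled fixed-effects fit, and per-individual fits combined
by inverse-variance averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from shapely.geometry import MultiPoint, Polygon

from .core import FitResult, KillSiteSet, Track
from .landscape import CovariateStack

__all__ = [
    "AvailabilityDomain", "RsfDesign", "build_mcp", "sample_rsf_available",
    "extract_point_covariates", "build_rsf_design", "fit_rsf",
    "inverse_variance_combine",
]

RIDGE_PENALTY = 1e-4


@dataclass
class AvailabilityDomain:
    """An animal's availability polygon: the convex hull of all its fixes."""

    animal_id: str
    polygon: Polygon

    @property
    def area(self) -> float:
        return float(self.polygon.area)


def build_mcp(track: Track) -> AvailabilityDomain:
    """100% minimum convex polygon around all fixes of a track."""
    if len(track) < 3:
        raise ValueError("MCP needs at least 3 fixes")
    hull = MultiPoint(list(zip(track.x, track.y))).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError(f"fixes of {track.animal_id!r} are collinear; "
                         "MCP undefined")
    return AvailabilityDomain(track.animal_id, hull)


def sample_rsf_available(domain: AvailabilityDomain, n_kills: int,
                         per_kill: int = 10, seed: int = 0) -> np.ndarray:
    """Uniform points inside the MCP by bounding-box rejection.

    Returns an ``(per_kill * n_kills, 2)`` array, reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    n = per_kill * n_kills
    xmin, ymin, xmax, ymax = domain.polygon.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        ok = shapely.contains_xy(domain.polygon, xs, ys)
        take = min(int(ok.sum()), n - filled)
        out[filled:filled + take, 0] = xs[ok][:take]
        out[filled:filled + take, 1] = ys[ok][:take]
        filled += take
    return out


@dataclass
class RsfDesign:
    """Used/available point design with extracted covariates."""

    rows: pd.DataFrame      # animal_id, case, x, y, covariates...
    formula: list[str]      # covariate columns (intercept added at fit time)

    @property
    def n_points(self) -> int:
        return len(self.rows)


def extract_point_covariates(points: pd.DataFrame, stack: CovariateStack,
                             scale_choice) -> pd.DataFrame:
    """Attach covariate columns to a point table (columns x, y).

    Percent-cover covariates are read from the focal variant at the chosen
    radius (column ``"<name>@<radius>"``); other layers at the point's cell.
    Raises if any point lies outside the raster extent, naming the row.
    """
    df = points.copy()
    ref = stack.reference
    x0, y0 = ref.origin
    j = np.floor((df["x"].to_numpy() - x0) / ref.resolution).astype(int)
    i = np.floor((df["y"].to_numpy() - y0) / ref.resolution).astype(int)
    ny, nx = ref.values.shape
    bad = (i < 0) | (i >= ny) | (j < 0) | (j >= nx)
    if bad.any():
        raise ValueError("point(s) outside extent at rows "
                         f"{[int(r) for r in np.flatnonzero(bad)[:5]]}")
    from .issa import normalize_covariate_spec
    for name, scale in normalize_covariate_spec(scale_choice):
        grid = stack.layer(name, scale)
        col = f"{name}@{scale}" if scale is not None else name
        df[col] = grid.values[i, j]
    return df


def build_rsf_design(kills: KillSiteSet, tracks: list[Track],
                     stack: CovariateStack, scale_choice,
                     per_kill: int = 10, seed: int = 0) -> RsfDesign:
    """Assemble the used/available design: each animal's kills plus
    ``per_kill`` uniform MCP points per kill."""
    rng = np.random.SeedSequence(seed)
    track_by_id = {t.animal_id: t for t in tracks}
    parts = []
    ids = list(kills.points["animal_id"].unique())
    child_seeds = rng.spawn(len(ids))
    for aid, ss in zip(ids, child_seeds):
        k = kills.points[kills.points["animal_id"] == aid]
        used = pd.DataFrame({"animal_id": aid, "case": 1,
                             "x": k["x"].to_numpy(), "y": k["y"].to_numpy()})
        domain = build_mcp(track_by_id[aid])
        av = sample_rsf_available(domain, len(k), per_kill,
                                  seed=ss.generate_state(1)[0] % (2**31))
        avail = pd.DataFrame({"animal_id": aid, "case": 0,
                              "x": av[:, 0], "y": av[:, 1]})
        parts += [used, avail]
    from .issa import normalize_covariate_spec
    pts = pd.concat(parts, ignore_index=True)
    pts = extract_point_covariates(pts, stack, scale_choice)
    formula = [f"{n}@{s}" if s is not None else n
               for n, s in normalize_covariate_spec(scale_choice)]
    return RsfDesign(pts, formula)


# ---------------------------------------------------------------------------
# logistic estimation
# ---------------------------------------------------------------------------

def _logistic_newton(X, y, penalty=0.0, max_iter=200, tol=1e-10):
    """Newton IRLS for logistic regression; optional ridge on slopes only."""
    k = X.shape[1]
    pen = np.full(k, penalty)
    pen[0] = 0.0    # never penalise the intercept
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p) - pen * beta
        W = p * (1 - p)
        info = (X * W[:, None]).T @ X + np.diag(pen)
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.linalg.norm(grad, ord=np.inf) < tol:
            break
    eta = X @ beta
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1 - p)
    info = (X * W[:, None]).T @ X + np.diag(pen)
    converged = np.linalg.norm(grad, ord=np.inf) < 1e-6
    return beta, ll, info, converged


def fit_rsf(design: RsfDesign, formula: list[str] | None = None,
            per_individual: bool = False) -> FitResult:
    """Logistic regression of used (1) vs available (0) points.

    The pooled tier fits one fixed-effects model with an intercept.  When
    separation prevents convergence, a weakly informative ridge penalty
    (1e-4 on the slopes) stabilises the fit and the result is flagged in
    ``diagnostics``.  With ``per_individual=True``, one model is fitted per
    animal and slope estimates are combined by inverse-variance averaging.
    """
    cols = formula if formula is not None else design.formula
    if per_individual:
        fits = []
        for aid, sub in design.rows.groupby("animal_id"):
            fits.append(fit_rsf(RsfDesign(sub.reset_index(drop=True), cols)))
        return inverse_variance_combine(fits)

    df = design.rows
    if df["case"].nunique() < 2:
        raise ValueError("design must contain both used and available points")
    X = np.column_stack([np.ones(len(df)), df[cols].to_numpy(float)])
    y = df["case"].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    names = ["intercept"] + list(cols)
    diagnostics = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smfit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = np.asarray(smfit.params)
        ll = float(smfit.llf)
        vcov = np.asarray(smfit.cov_params())
        converged = bool(smfit.mle_retvals.get("converged", False))
        info = np.linalg.inv(vcov)
    except Exception:
        converged, beta = False, np.full(X.shape[1], np.inf)
    if not converged or np.abs(beta).max() > 30:
        beta, ll, info, converged = _logistic_newton(X, y, penalty=RIDGE_PENALTY)
        diagnostics["ridge_fallback"] = True
        diagnostics["separation_suspected"] = True
    vcov = np.linalg.inv(info)
    idx = pd.Index(names)
    res = FitResult(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(np.sqrt(np.clip(np.diag(vcov), 0, None)), index=idx),
        llf=ll, nobs_units=len(df), model_family="logistic_rsf",
        converged=converged,
        vcov=pd.DataFrame(vcov, index=idx, columns=idx))
    res.diagnostics.update(diagnostics)
    return res


def inverse_variance_combine(fits: list[FitResult]) -> FitResult:
    """Combine per-individual fits: weights 1/SE² per coefficient."""
    if not fits:
        raise ValueError("no fits to combine")
    idx = fits[0].params.index
    coefs = np.array([f.params.reindex(idx).to_numpy() for f in fits])
    ses = np.array([f.bse.reindex(idx).to_numpy() for f in fits])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = 1.0 / ses**2
    wsum = np.nansum(w, axis=0)
    est = np.nansum(w * coefs, axis=0) / wsum
    se = np.sqrt(1.0 / wsum)
    return FitResult(
        params=pd.Series(est, index=idx), bse=pd.Series(se, index=idx),
        llf=float(sum(f.llf for f in fits)),
        nobs_units=int(sum(f.nobs_units for f in fits)),
        model_family=fits[0].model_family + "_per_individual",
        converged=all(f.converged for f in fits),
        diagnostics={"n_individuals": len(fits)})
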