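"""Integrated step selection analysis (iSSA).

An observed track is decomposed into *steps* (straight lines between
consecutive fixes).  Each retained used step is matched with J simulated
available steps sharing its start point, with lengths drawn from a gamma
distribution and turning angles from a von Mises distribution fitted to the
empirical used steps.  Habitat selection is then estimated by maximising
the conditional-logistic (strata softmax) likelihood

    l(beta) = sum_s [ eta_used(s) - log sum_j exp(eta_j(s)) ],

where eta = beta . x has no intercept (stratum intercepts cancel).  The
log of step length and the cosine of the turning angle enter as movement
adjustment terms.  A Poisson reformulation with one free intercept per
stratum — profiled out in closed form, the exact large-variance limit of
the random-stratum-intercept device — is provided as a cross-check; its
slope estimates coincide with the conditional fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import FitResult, Track
from .landscape import CovariateStack

MIN_STEP_LENGTH = 20.0       # metres; shorter displacements are stationary noise
KAPPA_CAP = 100.0

TERRAIN_LINE_COVARIATES = ("slope", "ruggedness", "tpi")

__all__ = [
    "Step", "StepDesign", "MovementKernel",
    "clean_and_build_steps", "fit_movement_kernel", "sample_available",
    "extract_step_covariates", "fit_conditional_logit", "fit_poisson_trick",
]


@dataclass
class Step:
    """One used step: start/end, length, turn, and the previous bearing the
    turn was measured against (NaN for the first retained step)."""

    animal_id: str
    start: tuple[float, float]
    end: tuple[float, float]
    length: float
    bearing: float
    turn: float            # radians in (-pi, pi]; NaN if undefined
    ref_bearing: float     # bearing of the previous retained step; NaN if none


@dataclass
class MovementKernel:
    """Empirical movement kernel: gamma step lengths, von Mises turns."""

    gamma_shape: float
    gamma_scale: float
    vm_kappa: float

    def __post_init__(self) -> None:
        if min(self.gamma_shape, self.gamma_scale) <= 0 or self.vm_kappa < 0:
            raise ValueError("kernel parameters must be positive")


@dataclass
class StepDesign:
    """Stratified used/available design.

    ``rows`` has one row per step with columns ``animal_id, stratum_id,
    case, x1, y1, x2, y2, sl, ta`` plus extracted covariates; every stratum
    holds exactly one used row (case=1) and J available rows.  ``formula``
    lists the covariate columns in fitting order (the movement adjustment
    terms ``log_sl`` and ``cos_ta`` are appended by covariate extraction).
    """

    rows: pd.DataFrame
    J: int
    formula: list[str]

    def __post_init__(self) -> None:
        counts = self.rows.groupby("stratum_id")["case"].agg(["sum", "count"])
        if not (counts["sum"] == 1).all():
            raise ValueError("every stratum must contain exactly one used step")
        if not (counts["count"] == self.J + 1).all():
            raise ValueError(f"every stratum must contain {self.J} available steps")

    @property
    def n_strata(self) -> int:
        return self.rows["stratum_id"].nunique()

    def matrices(self, formula: list[str] | None = None):
        """(X, case, stratum codes) sorted by stratum, for the optimisers."""
        cols = formula if formula is not None else self.formula
        df = self.rows.sort_values(["stratum_id", "case"],
                                   ascending=[True, False], kind="stable")
        X = df[cols].to_numpy(dtype=float)
        y = df["case"].to_numpy(dtype=float)
        strata = pd.factorize(df["stratum_id"])[0]
        return X, y, strata


# ---------------------------------------------------------------------------
# step construction
# ---------------------------------------------------------------------------

def _wrap_angle(a: np.ndarray | float):
    """Wrap to (-pi, pi]."""
    out = np.mod(np.asarray(a) + np.pi, 2 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return out


def clean_and_build_steps(track: Track, min_length: float = MIN_STEP_LENGTH,
                          rethread: bool = True) -> list[Step]:
    """Build used steps from a track, removing sub-threshold displacements.

    With ``rethread=True`` (default) a fix closer than ``min_length`` to the
    last retained fix is dropped and the next step starts from that retained
    fix, so turning angles stay defined along the retained chain.  With
    ``rethread=False`` short steps are simply deleted, breaking the chain
    (the following step then has an undefined turn).
    """
    if len(track) < 3:
        raise ValueError("track needs at least 3 fixes")
    xs, ys = track.x, track.y

    if rethread:
        keep = [0]
        for i in range(1, len(track)):
            d = np.hypot(xs[i] - xs[keep[-1]], ys[i] - ys[keep[-1]])
            if d >= min_length:
                keep.append(i)
        pairs = [(keep[k], keep[k + 1]) for k in range(len(keep) - 1)]
        chain_breaks = [False] * len(pairs)
    else:
        pairs, chain_breaks = [], []
        prev_kept = None
        for i in range(len(track) - 1):
            d = np.hypot(xs[i + 1] - xs[i], ys[i + 1] - ys[i])
            if d >= min_length:
                pairs.append((i, i + 1))
                chain_breaks.append(prev_kept is not None and prev_kept != i)
                prev_kept = i + 1

    if len(pairs) < 2:
        raise ValueError("fewer than 2 retained steps after filtering")

    steps: list[Step] = []
    prev_bearing = np.nan
    for (i, j), broke in zip(pairs, chain_breaks):
        dx, dy = xs[j] - xs[i], ys[j] - ys[i]
        bearing = float(np.arctan2(dy, dx))
        if broke:
            prev_bearing = np.nan
        turn = (float(_wrap_angle(bearing - prev_bearing))
                if np.isfinite(prev_bearing) else np.nan)
        steps.append(Step(track.animal_id, (float(xs[i]), float(ys[i])),
                          (float(xs[j]), float(ys[j])),
                          float(np.hypot(dx, dy)), bearing, turn,
                          prev_bearing))
        prev_bearing = bearing
    return steps


# ---------------------------------------------------------------------------
# movement kernel
# ---------------------------------------------------------------------------

def _kappa_mle(turns: np.ndarray) -> float:
    """Von Mises concentration MLE with mean direction fixed at zero."""
    r = float(np.mean(np.cos(turns)))
    if r <= 0:
        return 0.0
    a1 = lambda k: special.i1(k) / special.i0(k)
    if a1(KAPPA_CAP) <= r:
        warnings.warn(f"turn concentration at cap kappa={KAPPA_CAP}",
                      stacklevel=2)
        return KAPPA_CAP
    return float(optimize.brentq(lambda k: a1(k) - r, 1e-10, KAPPA_CAP))


def fit_movement_kernel(used_steps: list[Step]) -> MovementKernel:
    """MLE gamma fit to retained step lengths and von Mises concentration
    (mean direction 0) to defined turning angles."""
    lengths = np.array([s.length for s in used_steps])
    if len(lengths) < 30:
        raise ValueError("need at least 30 retained steps to fit the kernel")
    if np.ptp(lengths) == 0:
        raise ValueError("degenerate step lengths (all equal)")
    shape, _, scale = stats.gamma.fit(lengths, floc=0)
    turns = np.array([s.turn for s in used_steps if np.isfinite(s.turn)])
    kappa = _kappa_mle(turns) if len(turns) else 0.0
    return MovementKernel(float(shape), float(scale), max(kappa, 1e-8))


# ---------------------------------------------------------------------------
# availability sampling
# ---------------------------------------------------------------------------

def sample_available(used_steps: list[Step], kernel: MovementKernel,
                     extent: tuple[float, float, float, float],
                     J: int = 10, seed: int = 0,
                     max_retries: int = 100) -> StepDesign:
    """Pair each used step with J available steps from the fitted kernel.

    Available lengths are gamma draws, turns von Mises draws about the
    previous retained bearing (uniform when that bearing is undefined, i.e.
    the first stratum of a chain).  Endpoints falling outside ``extent`` are
    redrawn up to ``max_retries`` times; a stratum whose available set
    cannot be completed is dropped and counted.
    """
    if J < 1:
        raise ValueError("J must be at least 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    n = len(used_steps)
    sx = np.array([s.start[0] for s in used_steps])
    sy = np.array([s.start[1] for s in used_steps])
    ref_b = np.array([s.ref_bearing for s in used_steps])
    has_ref = np.isfinite(ref_b)

    sl = rng.gamma(kernel.gamma_shape, kernel.gamma_scale, (n, J))
    ta = np.where(has_ref[:, None],
                  _wrap_angle(rng.vonmises(0.0, kernel.vm_kappa, (n, J))),
                  np.nan)
    bearing = np.where(has_ref[:, None], ref_b[:, None] + ta,
                       rng.uniform(-np.pi, np.pi, (n, J)))
    ex = sx[:, None] + sl * np.cos(bearing)
    ey = sy[:, None] + sl * np.sin(bearing)
    bad = ~((xmin <= ex) & (ex < xmax) & (ymin <= ey) & (ey < ymax))
    for _ in range(max_retries):
        if not bad.any():
            break
        ii, jj = np.nonzero(bad)
        m = len(ii)
        sl_r = rng.gamma(kernel.gamma_shape, kernel.gamma_scale, m)
        hr = has_ref[ii]
        ta_r = np.where(hr, _wrap_angle(rng.vonmises(0.0, kernel.vm_kappa, m)),
                        np.nan)
        b_r = np.where(hr, ref_b[ii] + ta_r, rng.uniform(-np.pi, np.pi, m))
        sl[ii, jj], ta[ii, jj] = sl_r, ta_r
        ex[ii, jj] = sx[ii] + sl_r * np.cos(b_r)
        ey[ii, jj] = sy[ii] + sl_r * np.sin(b_r)
        bad = ~((xmin <= ex) & (ex < xmax) & (ymin <= ey) & (ey < ymax))
    keep = ~bad.any(axis=1)
    dropped = int(n - keep.sum())
    if dropped:
        warnings.warn(f"dropped {dropped} strata after retry exhaustion",
                      stacklevel=2)

    idx = np.flatnonzero(keep)
    animal = np.array([s.animal_id for s in used_steps], dtype=object)
    used_df = pd.DataFrame({
        "animal_id": animal[idx], "stratum_id": idx, "case": 1,
        "x1": sx[idx], "y1": sy[idx],
        "x2": [used_steps[i].end[0] for i in idx],
        "y2": [used_steps[i].end[1] for i in idx],
        "sl": [used_steps[i].length for i in idx],
        "ta": [used_steps[i].turn for i in idx],
    })
    avail_df = pd.DataFrame({
        "animal_id": np.repeat(animal[idx], J),
        "stratum_id": np.repeat(idx, J), "case": 0,
        "x1": np.repeat(sx[idx], J), "y1": np.repeat(sy[idx], J),
        "x2": ex[idx].ravel(), "y2": ey[idx].ravel(),
        "sl": sl[idx].ravel(), "ta": ta[idx].ravel(),
    })
    rows = (pd.concat([used_df, avail_df], ignore_index=True)
            .sort_values(["stratum_id", "case"], ascending=[True, False],
                         kind="stable").reset_index(drop=True))
    design = StepDesign(rows, J=J, formula=[])
    design.rows.attrs["dropped_strata"] = dropped
    return design


# ---------------------------------------------------------------------------
# covariate extraction
# ---------------------------------------------------------------------------

def bresenham_cells(i1: int, j1: int, i2: int, j2: int) -> list[tuple[int, int]]:
    """Integer grid cells traversed by the segment, endpoints inclusive."""
    cells = []
    di, dj = abs(i2 - i1), abs(j2 - j1)
    si = 1 if i2 >= i1 else -1
    sj = 1 if j2 >= j1 else -1
    err = dj - di
    i, j = i1, j1
    while True:
        cells.append((i, j))
        if i == i2 and j == j2:
            break
        e2 = 2 * err
        if e2 > -di:
            err -= di
            j += sj
        if e2 < dj:
            err += dj
            i += si
    return cells


def normalize_covariate_spec(spec) -> list[tuple[str, int | None]]:
    """Accept a dict name->scale or an iterable of (name, scale) pairs."""
    if isinstance(spec, dict):
        return [(n, s) for n, s in spec.items()]
    return [(n, s) for n, s in spec]


def extract_step_covariates(design: StepDesign, stack: CovariateStack,
                            scale_choice,
                            line_covariates: tuple[str, ...] = TERRAIN_LINE_COVARIATES,
                            ) -> StepDesign:
    """Attach covariate columns to a step design.

    ``scale_choice`` maps covariate names to a focal-window radius (metres)
    for percent-cover layers, or ``None`` for plain layers (a dict or a
    list of (name, scale) pairs — the latter allows several scales of the
    same covariate side by side).  Covariates in
    ``line_covariates`` (terrain metrics) are averaged over the grid cells
    traversed by the start-to-end segment; everything else is read at the
    end cell.  Columns for percent-cover variants are named
    ``"<name>@<radius>"``.  The movement adjustment columns ``log_sl`` and
    ``cos_ta`` are appended; in strata whose turn is undefined (first step
    of a chain) ``cos_ta`` is set to a stratum-constant 0, which cancels in
    the conditional likelihood.
    """
    df = design.rows.copy()
    ref = stack.reference
    i1, j1 = _cells(ref, df["x1"], df["y1"])
    i2, j2 = _cells(ref, df["x2"], df["y2"])

    formula: list[str] = []
    for name, scale in normalize_covariate_spec(scale_choice):
        grid = stack.layer(name, scale)
        col = f"{name}@{scale}" if scale is not None else name
        if name in line_covariates:
            vals = np.empty(len(df))
            for r in range(len(df)):
                cells = bresenham_cells(i1[r], j1[r], i2[r], j2[r])
                ii = np.fromiter((c[0] for c in cells), int)
                jj = np.fromiter((c[1] for c in cells), int)
                vals[r] = grid.values[ii, jj].mean()
            df[col] = vals
        else:
            df[col] = grid.values[i2, j2]
        formula.append(col)

    df["log_sl"] = np.log(np.maximum(df["sl"].to_numpy(), 1e-12))
    # a stratum whose turn is undefined (first step of a chain) has NaN ta on
    # used and available rows alike; zeroing makes cos_ta stratum-constant
    # there, so the term cancels from the conditional likelihood
    cos_ta = np.cos(df["ta"].to_numpy())
    df["cos_ta"] = np.where(np.isfinite(cos_ta), cos_ta, 0.0)
    formula += ["log_sl", "cos_ta"]

    return StepDesign(df, J=design.J, formula=formula)


def _cells(ref, xs, ys):
    x0, y0 = ref.origin
    j = np.floor((np.asarray(xs) - x0) / ref.resolution).astype(int)
    i = np.floor((np.asarray(ys) - y0) / ref.resolution).astype(int)
    ny, nx = ref.values.shape
    if np.any((i < 0) | (i >= ny) | (j < 0) | (j >= nx)):
        raise ValueError("step endpoint outside raster extent")
    return i, j


# ---------------------------------------------------------------------------
# conditional-logit / Poisson estimation
# ---------------------------------------------------------------------------

def _segment_logsumexp(eta: np.ndarray, strata: np.ndarray, n_strata: int):
    """Per-stratum logsumexp plus softmax probabilities (strata sorted)."""
    m = np.full(n_strata, -np.inf)
    np.maximum.at(m, strata, eta)
    z = np.zeros(n_strata)
    np.add.at(z, strata, np.exp(eta - m[strata]))
    lse = m + np.log(z)
    p = np.exp(eta - lse[strata])
    return lse, p


def _clogit_parts(beta, X, y, strata, n_strata):
    eta = X @ beta
    lse, p = _segment_logsumexp(eta, strata, n_strata)
    ll = float(eta[y == 1].sum() - lse.sum())
    grad = X.T @ (y - p)
    # observed information: sum_s [ sum_j p x x' - m_s m_s' ]
    pw = X * p[:, None]
    H1 = X.T @ pw
    M = np.zeros((n_strata, X.shape[1]))
    np.add.at(M, strata, pw)
    info = H1 - M.T @ M
    return ll, grad, info


def _newton(obj, k, max_iter=500, tol=1e-8):
    """Damped Newton ascent from beta = 0 with gradient-norm stopping."""
    beta = np.zeros(k)
    ll, grad, info = obj(beta)
    for _ in range(max_iter):
        if np.linalg.norm(grad, ord=np.inf) < tol:
            return beta, ll, info, True
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            step = grad
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new, grad_new, info_new = obj(cand)
            if ll_new > ll - 1e-12:
                beta, ll, grad, info = cand, ll_new, grad_new, info_new
                break
            t *= 0.5
        else:
            break
    converged = np.linalg.norm(grad, ord=np.inf) < tol
    return beta, ll, info, converged


def _separation_diagnostic(X, y, strata, formula):
    """Name covariates that perfectly rank used above available in all strata."""
    culprits = []
    used = y == 1
    for c, name in enumerate(formula):
        col = X[:, c]
        used_vals = np.zeros(strata.max() + 1)
        used_vals[strata[used]] = col[used]
        top = col >= used_vals[strata] - 1e-12
        bottom = col <= used_vals[strata] + 1e-12
        per_top = np.ones(strata.max() + 1, bool)
        per_bot = np.ones(strata.max() + 1, bool)
        np.logical_and.at(per_top, strata, top)
        np.logical_and.at(per_bot, strata, bottom)
        if per_top.all() or per_bot.all():
            culprits.append(name)
    return culprits


def _finish(beta, ll, info, converged, formula, n_units, family):
    try:
        vcov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    except np.linalg.LinAlgError:
        vcov = np.full((len(beta),) * 2, np.nan)
        se = np.full(len(beta), np.nan)
    idx = pd.Index(formula)
    return FitResult(
        params=pd.Series(beta, index=idx), bse=pd.Series(se, index=idx),
        llf=ll, nobs_units=n_units, model_family=family, converged=converged,
        vcov=pd.DataFrame(vcov, index=idx, columns=idx))


def _diagnose(res: FitResult, X, y, strata, cols) -> FitResult:
    """Flag (quasi-)separation: under separation the gradient also vanishes
    as |beta| grows, so a huge estimate with near-zero deviance must not be
    reported as converged."""
    if not res.converged or np.abs(res.params.to_numpy()).max() > 10:
        culprits = _separation_diagnostic(X, y, strata, cols)
        if culprits:
            res.converged = False
            res.diagnostics["separation"] = culprits
    return res


def fit_conditional_logit(design: StepDesign,
                          formula: list[str] | None = None) -> FitResult:
    """Maximise the stratified softmax likelihood; SEs from the inverse
    observed information.  Non-convergence is flagged, with a diagnostic
    naming any covariate that separates used from available in every
    stratum."""
    cols = formula if formula is not None else design.formula
    X, y, strata = design.matrices(cols)
    n_strata = strata.max() + 1
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    obj = lambda b: _clogit_parts(b, X, y, strata, n_strata)
    beta, ll, info, converged = _newton(obj, X.shape[1])
    return _diagnose(_finish(beta, ll, info, converged, cols, n_strata,
                             "conditional_logit"), X, y, strata, cols)


def fit_poisson_trick(design: StepDesign,
                      formula: list[str] | None = None) -> FitResult:
    """Poisson reformulation with one free intercept per stratum.

    For fixed slopes the Poisson likelihood in the stratum intercepts
    alpha_s has the closed-form maximiser alpha_s = -log sum_j exp(eta_js)
    (each stratum's expected count matches its single used step); the
    profiled objective is optimised over the slopes.  Slope estimates and
    their SEs coincide with the conditional logit; log-likelihoods differ
    by the data-independent constant -n_strata.
    """
    cols = formula if formula is not None else design.formula
    X, y, strata = design.matrices(cols)
    n_strata = strata.max() + 1

    def obj(beta):
        eta = X @ beta
        lse, _ = _segment_logsumexp(eta, strata, n_strata)
        alpha = -lse
        mu = np.exp(alpha[strata] + eta)
        ll = float(np.sum(y * (alpha[strata] + eta)) - mu.sum())
        resid = y - mu
        grad = X.T @ resid
        # profiled information equals the conditional-logit information
        pw = X * mu[:, None]
        M = np.zeros((n_strata, X.shape[1]))
        np.add.at(M, strata, pw)
        info = X.T @ pw - M.T @ M
        return ll, grad, info

    beta, ll, info, converged = _newton(obj, X.shape[1])
    return _diagnose(_finish(beta, ll, info, converged, cols, n_strata,
                             "poisson_trick"), X, y, strata, cols)
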