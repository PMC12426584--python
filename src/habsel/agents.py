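"""Agent-based simulation of tracks, kill sites, and incident points.

The simulator is the generative inverse of the fitting pipeline: each
2-hour step is chosen among candidate endpoints proposed from the gamma /
von Mises movement kernel with probability proportional to
exp(beta_move . x) at the endpoint; kill sites are drawn inside each
animal's MCP with density proportional to exp(beta_feed . x); incident
points are uniform proposals thinned by a logistic function of the two
SD-rescaled suitability surfaces.  Because the generative parameters are
known, parameter recovery by the fitting modules is directly testable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import IncidentSet, KillSiteSet, Track, TruthParams
from .landscape import CovariateStack, RasterGrid
from .rsf import build_mcp

# Discretization of the availability kernel while simulating.  Choosing one
# of C kernel draws by softmax converges to the continuous exp-weighted
# kernel only as C grows; C=200 keeps the residual attenuation of selection
# coefficients well under the estimation SE at the cohort sizes used here.
CANDIDATES_PER_STEP = 200
WILD_PREY_PROB = 0.977
MIN_ACCEPT_RATE = 1e-4

__all__ = ["simulate_track", "simulate_kills", "simulate_incidents",
           "simulate_cohort"]


def _beta_arrays(stack: CovariateStack, beta: dict[str, float]):
    """Resolve covariate names (``name`` or ``name@radius``) to arrays."""
    grids, weights = [], []
    for name, w in beta.items():
        if "@" in name:
            base, radius = name.rsplit("@", 1)
            grids.append(stack.layer(base, int(radius)).values)
        else:
            grids.append(stack.layer(name).values)
        weights.append(float(w))
    return grids, np.asarray(weights)


def _eta_grid(stack: CovariateStack, beta: dict[str, float]) -> np.ndarray:
    grids, weights = _beta_arrays(stack, beta)
    eta = np.zeros(stack.reference.shape)
    for g, w in zip(grids, weights):
        eta += w * g
    return eta


def simulate_track(stack: CovariateStack, truth: TruthParams, n_steps: int,
                   start: tuple[float, float], seed: int,
                   animal_id: str = "A0", age_sex_class: str = "AF",
                   n_candidates: int = CANDIDATES_PER_STEP,
                   max_retries: int = 100) -> Track:
    """Simulate a selection-biased correlated random walk.

    At each step ``n_candidates`` endpoints are proposed (gamma lengths, von
    Mises turns about the previous bearing; the first turn is uniform) and
    one is chosen with probability proportional to exp(beta_move . x) at
    the endpoint.  Candidates leaving the landscape extent are redrawn up
    to ``max_retries`` rounds; exhausting the retries aborts with an error
    naming the fix index.  Identical seed gives an identical track.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    ref = stack.reference
    xmin, ymin, xmax, ymax = ref.extent
    if not (xmin <= start[0] < xmax and ymin <= start[1] < ymax):
        raise ValueError("start must lie inside the landscape extent")
    rng = np.random.default_rng(seed)
    eta = _eta_grid(stack, truth.beta_move)
    res, (x0g, y0g) = ref.resolution, ref.origin

    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    xs[0], ys[0] = start
    heading = rng.uniform(-np.pi, np.pi)
    for i in range(n_steps):
        sl = rng.gamma(truth.gamma_shape, truth.gamma_scale, n_candidates)
        if i == 0:
            turn = rng.uniform(-np.pi, np.pi, n_candidates)
        else:
            turn = rng.vonmises(0.0, truth.vm_kappa, n_candidates)
        b = heading + turn
        cx = xs[i] + sl * np.cos(b)
        cy = ys[i] + sl * np.sin(b)
        bad = ~((xmin <= cx) & (cx < xmax) & (ymin <= cy) & (cy < ymax))
        tries = 0
        while bad.any():
            tries += 1
            if tries > max_retries:
                raise RuntimeError(
                    f"candidate endpoints stuck outside extent at fix {i}")
            m = int(bad.sum())
            sl_r = rng.gamma(truth.gamma_shape, truth.gamma_scale, m)
            turn_r = (rng.uniform(-np.pi, np.pi, m) if i == 0
                      else rng.vonmises(0.0, truth.vm_kappa, m))
            b_r = heading + turn_r
            cx[bad] = xs[i] + sl_r * np.cos(b_r)
            cy[bad] = ys[i] + sl_r * np.sin(b_r)
            b[bad] = b_r
            bad = ~((xmin <= cx) & (cx < xmax) & (ymin <= cy) & (cy < ymax))
        jj = np.floor((cx - x0g) / res).astype(int)
        ii = np.floor((cy - y0g) / res).astype(int)
        w = eta[ii, jj]
        w = np.exp(w - w.max())
        choice = rng.choice(n_candidates, p=w / w.sum())
        xs[i + 1], ys[i + 1] = cx[choice], cy[choice]
        heading = float(np.arctan2(ys[i + 1] - ys[i], xs[i + 1] - xs[i]))

    t = truth.fix_interval * np.arange(n_steps + 1)
    return Track(animal_id, age_sex_class, t, xs, ys)


def simulate_kills(track: Track, stack: CovariateStack, truth: TruthParams,
                   n_kills: int, seed: int) -> KillSiteSet:
    """Draw kill sites inside the track's MCP with density proportional to
    exp(beta_feed . x), by rejection sampling against the cellwise maximum
    weight.  Raises when the acceptance rate collapses (advise smaller
    |beta_feed|)."""
    if n_kills == 0:
        return KillSiteSet(pd.DataFrame(
            columns=["animal_id", "x", "y", "prey_class"]))
    rng = np.random.default_rng(seed)
    domain = build_mcp(track)
    eta = _eta_grid(stack, truth.beta_feed)
    ref = stack.reference
    res, (x0g, y0g) = ref.resolution, ref.origin
    xminb, yminb, xmaxb, ymaxb = domain.polygon.bounds
    eta_max = float(eta.max())

    import shapely
    pts_x, pts_y = [], []
    proposals = 0
    while len(pts_x) < n_kills:
        m = max(4 * (n_kills - len(pts_x)), 256)
        proposals += m
        xs = rng.uniform(xminb, xmaxb, m)
        ys = rng.uniform(yminb, ymaxb, m)
        u = rng.random(m)
        inside = shapely.contains_xy(domain.polygon, xs, ys)
        jj = np.clip(np.floor((xs - x0g) / res).astype(int), 0,
                     ref.shape[1] - 1)
        ii = np.clip(np.floor((ys - y0g) / res).astype(int), 0,
                     ref.shape[0] - 1)
        acc = inside & (u < np.exp(eta[ii, jj] - eta_max))
        pts_x += list(xs[acc])
        pts_y += list(ys[acc])
        if proposals > max(n_kills, 1) / MIN_ACCEPT_RATE:
            raise RuntimeError(
                "kill-site acceptance rate below 1e-4; reduce |beta_feed|")
    pts_x, pts_y = pts_x[:n_kills], pts_y[:n_kills]
    prey = np.where(rng.random(n_kills) < WILD_PREY_PROB, "wild", "domestic")
    return KillSiteSet(pd.DataFrame({
        "animal_id": track.animal_id, "x": pts_x, "y": pts_y,
        "prey_class": prey}))


def simulate_incidents(move_rescaled: RasterGrid, feed_rescaled: RasterGrid,
                       conflict_coefs: tuple[float, float, float],
                       n_incidents: int, seed: int,
                       incident_type: str = "livestock") -> IncidentSet:
    """Thin uniform proposals over the extent by a logistic function of the
    two SD-rescaled suitability values: keep with probability
    sigmoid(intercept + a_feed * feed + b_move * move)."""
    rng = np.random.default_rng(seed)
    intercept, a_feed, b_move = conflict_coefs
    xmin, ymin, xmax, ymax = move_rescaled.extent
    xs_out, ys_out = [], []
    proposals = 0
    while len(xs_out) < n_incidents:
        m = max(4 * (n_incidents - len(xs_out)), 256)
        proposals += m
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        lin = (intercept + a_feed * feed_rescaled.value_at(xs, ys)
               + b_move * move_rescaled.value_at(xs, ys))
        keep = rng.random(m) < 1.0 / (1.0 + np.exp(-lin))
        xs_out += list(xs[keep])
        ys_out += list(ys[keep])
        if proposals > max(n_incidents, 1) / MIN_ACCEPT_RATE:
            raise RuntimeError("incident acceptance rate below 1e-4")
    return IncidentSet(pd.DataFrame({
        "x": xs_out[:n_incidents], "y": ys_out[:n_incidents],
        "type": incident_type}))


def simulate_cohort(stack: CovariateStack, truth_by_class: dict[str, TruthParams],
                    n_animals: dict[str, int], n_steps: int, n_kills: int,
                    seed: int) -> tuple[list[Track], KillSiteSet]:
    """Simulate a cohort: per age-sex class, ``n_animals[cls]`` tracks of
    ``n_steps`` steps each with ``n_kills`` kill sites, from class-specific
    truth parameters.  Start points are drawn uniformly over the central
    half of the landscape so tracks rarely pin against the boundary."""
    ss = np.random.SeedSequence(seed)
    ref = stack.reference
    xmin, ymin, xmax, ymax = ref.extent
    w, h = xmax - xmin, ymax - ymin
    tracks: list[Track] = []
    kill_parts = []
    idx = 0
    classes = sorted(n_animals)
    total = sum(n_animals.values())
    children = ss.spawn(total)
    for cls in classes:
        truth = truth_by_class[cls]
        for a in range(n_animals[cls]):
            child = children[idx]
            s1, s2, s3 = [int(s.generate_state(1)[0] % (2**31))
                          for s in child.spawn(3)]
            start_rng = np.random.default_rng(s1)
            start = (xmin + w * start_rng.uniform(0.25, 0.75),
                     ymin + h * start_rng.uniform(0.25, 0.75))
            tr = simulate_track(stack, truth, n_steps, start, seed=s2,
                                animal_id=f"{cls}{a:02d}", age_sex_class=cls)
            tracks.append(tr)
            if n_kills > 0:
                kill_parts.append(
                    simulate_kills(tr, stack, truth, n_kills, seed=s3).points)
            idx += 1
    kills = KillSiteSet(pd.concat(kill_parts, ignore_index=True)
                        if kill_parts else
                        pd.DataFrame(columns=["animal_id", "x", "y",
                                              "prey_class"]))
    return tracks, kills
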