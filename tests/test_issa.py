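"""Step construction, movement kernel, availability sampling, and the
conditional-logit / Poisson estimators, checked against an independent
softmax-likelihood oracle and statsmodels' conditional logit."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import habsel as hs
from habsel.core import Track
from habsel.issa import (MovementKernel, StepDesign, bresenham_cells,
                         clean_and_build_steps, extract_step_covariates,
                         fit_conditional_logit, fit_movement_kernel,
                         fit_poisson_trick, sample_available)


def make_track(xs, ys, animal_id="T"):
    xs = np.asarray(xs, dtype=float)
    return Track(animal_id, "AF", np.arange(len(xs)) * 2.0, xs,
                 np.asarray(ys, dtype=float))


# ----------------------------------------------------------- step building

def test_all_long_steps_retained():
    xs = np.arange(10) * 100.0
    steps = clean_and_build_steps(make_track(xs, np.zeros(10)))
    assert len(steps) == 9
    assert all(s.length == pytest.approx(100.0) for s in steps)


def test_micro_steps_rethreaded_hand_count():
    # 10 fixes alternating +5 m and +500 m eastward displacements;
    # retained fixes are x = 0, 505, 1010, 1515, 2020 -> 4 steps
    xs = np.cumsum([0, 5, 500, 5, 500, 5, 500, 5, 500, 5])
    steps = clean_and_build_steps(make_track(xs, np.zeros(10)))
    assert len(steps) == 4
    assert [round(s.length) for s in steps] == [505, 505, 505, 505]


def test_collinear_track_has_zero_turns():
    xs = np.arange(8) * 100.0
    steps = clean_and_build_steps(make_track(xs, np.zeros(8)))
    assert np.isnan(steps[0].turn)
    assert all(s.turn == pytest.approx(0.0) for s in steps[1:])


def test_drop_mode_breaks_chain():
    xs = np.array([0.0, 100.0, 105.0, 205.0, 305.0])
    steps = clean_and_build_steps(make_track(xs, np.zeros(5)),
                                  rethread=False)
    # the 100->105 step is deleted; the following step's turn is undefined
    assert len(steps) == 3
    assert np.isnan(steps[1].turn)


def test_too_few_retained_steps_errors():
    with pytest.raises(ValueError, match="retained"):
        clean_and_build_steps(make_track([0.0, 1.0, 2.0], [0.0, 0.0, 0.0]))


# --------------------------------------------------------- movement kernel

def test_gamma_mle_consistency():
    rng = np.random.default_rng(6)
    xs = np.concatenate([[0], np.cumsum(rng.gamma(2.0, 300.0, 5000))])
    kern = fit_movement_kernel(clean_and_build_steps(make_track(xs, np.zeros(len(xs)))))
    assert kern.gamma_shape == pytest.approx(2.0, abs=0.1)
    assert kern.gamma_scale == pytest.approx(300.0, rel=0.1)


def test_kappa_capped_for_collinear_track():
    rng = np.random.default_rng(30)
    xs = np.concatenate([[0], np.cumsum(rng.gamma(2.0, 300.0, 99))])
    steps = clean_and_build_steps(make_track(xs, np.zeros(100)))
    with pytest.warns(UserWarning, match="cap"):
        kern = fit_movement_kernel(steps)
    assert kern.vm_kappa == pytest.approx(100.0)


def test_kappa_near_zero_for_uniform_turns():
    rng = np.random.default_rng(7)
    n = 5000
    turns = rng.uniform(-np.pi, np.pi, n)
    lengths = rng.gamma(2.0, 300.0, n)
    x, y, b = [0.0], [0.0], 0.0
    for sl, ta in zip(lengths, turns):
        b = b + ta
        x.append(x[-1] + sl * np.cos(b))
        y.append(y[-1] + sl * np.sin(b))
    kern = fit_movement_kernel(clean_and_build_steps(make_track(x, y)))
    assert abs(kern.vm_kappa) < 0.05


def test_degenerate_lengths_error():
    steps = clean_and_build_steps(make_track(np.arange(40) * 100.0,
                                             np.zeros(40)))
    for s in steps:
        s.length = 100.0
    with pytest.raises(ValueError, match="degenerate"):
        fit_movement_kernel(steps)


# ----------------------------------------------------- availability design

@pytest.fixture(scope="module")
def hundred_steps():
    rng = np.random.default_rng(8)
    n = 130
    xs = 50000.0 + np.cumsum(rng.gamma(2.0, 300.0, n) * np.cos(rng.uniform(-np.pi, np.pi, n)))
    ys = 50000.0 + np.cumsum(rng.gamma(2.0, 300.0, n) * np.sin(rng.uniform(-np.pi, np.pi, n)))
    steps = clean_and_build_steps(make_track(xs, ys))
    assert len(steps) >= 100
    return steps[:100]


def test_design_row_counts(hundred_steps):
    kern = MovementKernel(2.0, 300.0, 0.5)
    design = sample_available(hundred_steps, kern, (0, 0, 1e5, 1e5),
                              J=10, seed=9)
    assert len(design.rows) == 1100
    assert design.n_strata == 100


def test_design_j1(hundred_steps):
    kern = MovementKernel(2.0, 300.0, 0.5)
    design = sample_available(hundred_steps[:5], kern, (0, 0, 1e5, 1e5),
                              J=1, seed=9)
    counts = design.rows.groupby("stratum_id").size()
    assert (counts == 2).all()


def test_available_sampling_deterministic(hundred_steps):
    kern = MovementKernel(2.0, 300.0, 0.5)
    a = sample_available(hundred_steps, kern, (0, 0, 1e5, 1e5), J=10, seed=10)
    b = sample_available(hundred_steps, kern, (0, 0, 1e5, 1e5), J=10, seed=10)
    pd.testing.assert_frame_equal(a.rows, b.rows)


# ------------------------------------------------------------- extraction

def test_bresenham_straight_and_diagonal():
    assert bresenham_cells(0, 0, 0, 3) == [(0, 0), (0, 1), (0, 2), (0, 3)]
    assert bresenham_cells(0, 0, 3, 3) == [(0, 0), (1, 1), (2, 2), (3, 3)]


def test_extraction_uniform_raster_constant(zstack, movement_design):
    ref = zstack.reference
    uni = hs.CovariateStack(layers={"flat": ref.like(np.full(ref.shape, 3.5),
                                                     "flat")})
    d = extract_step_covariates(movement_design, uni, [("flat", None)],
                                line_covariates=())
    assert (d.rows["flat"] == 3.5).all()


def test_line_average_matches_hand_bresenham():
    vals = np.arange(100, dtype=float).reshape(10, 10)
    g = hs.RasterGrid(vals, resolution=30.0, name="slope")
    stack = hs.CovariateStack(layers={"slope": g})
    rows = pd.DataFrame([
        dict(animal_id="T", stratum_id=0, case=1,
             x1=15.0, y1=15.0, x2=135.0, y2=105.0, sl=150.0, ta=0.0)])
    design = StepDesign.__new__(StepDesign)
    design.rows, design.J, design.formula = rows, 0, []
    out = extract_step_covariates(design, stack, [("slope", None)])
    # segment from cell (0,0) to (3,4): Bresenham cells hand-enumerated
    cells = [(0, 0), (1, 1), (1, 2), (2, 3), (3, 4)]
    expected = np.mean([vals[i, j] for i, j in cells])
    assert out.rows["slope"].iloc[0] == pytest.approx(expected)


def test_zero_length_segment_equals_endpoint_value():
    vals = np.arange(25, dtype=float).reshape(5, 5)
    g = hs.RasterGrid(vals, resolution=30.0, name="tpi")
    stack = hs.CovariateStack(layers={"tpi": g})
    rows = pd.DataFrame([dict(animal_id="T", stratum_id=0, case=1,
                              x1=75.0, y1=75.0, x2=75.0, y2=75.0,
                              sl=0.0, ta=0.0)])
    design = StepDesign.__new__(StepDesign)
    design.rows, design.J, design.formula = rows, 0, []
    out = extract_step_covariates(design, stack, [("tpi", None)])
    assert out.rows["tpi"].iloc[0] == vals[2, 2]


# ------------------------------------------------- conditional logit oracle

def oracle_negll(beta, X, y, strata):
    """Independent softmax likelihood: plain per-stratum loops."""
    ll = 0.0
    for s in np.unique(strata):
        rows = np.nonzero(strata == s)[0]
        eta = X[rows] @ beta
        used = rows[y[rows] == 1][0]
        ll += X[used] @ beta - np.log(np.sum(np.exp(eta - eta.max()))) \
            - eta.max()
    return -ll


def random_design(n_strata=50, J=2, k=2, seed=12, beta=None):
    rng = np.random.default_rng(seed)
    beta = np.zeros(k) if beta is None else np.asarray(beta)
    rows = []
    for s in range(n_strata):
        X = rng.standard_normal((J + 1, k))
        p = np.exp(X @ beta)
        used = rng.choice(J + 1, p=p / p.sum())
        for r in range(J + 1):
            rows.append(dict(animal_id="A", stratum_id=s,
                             case=int(r == used),
                             x1=0.0, y1=0.0, x2=0.0, y2=0.0, sl=1.0, ta=0.0,
                             **{f"c{t}": X[r, t] for t in range(k)}))
    return StepDesign(pd.DataFrame(rows), J=J,
                      formula=[f"c{t}" for t in range(k)])


def test_uninformative_design_gives_zero_beta():
    rng = np.random.default_rng(13)
    rows = []
    for s in range(30):
        v = rng.standard_normal()
        for r in range(11):
            rows.append(dict(animal_id="A", stratum_id=s, case=int(r == 0),
                             x1=0, y1=0, x2=0, y2=0, sl=1.0, ta=0.0, c0=v))
    design = StepDesign(pd.DataFrame(rows), J=10, formula=["c0"])
    fit = fit_conditional_logit(design)
    assert fit.params["c0"] == pytest.approx(0.0, abs=1e-8)
    assert fit.llf == pytest.approx(-30 * np.log(11))


def test_conditional_logit_matches_softmax_oracle():
    design = random_design(beta=[0.8, -0.5])
    fit = fit_conditional_logit(design)
    X, y, strata = design.matrices()
    res = minimize(oracle_negll, np.zeros(2), args=(X, y, strata),
                   method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    np.testing.assert_allclose(fit.params.to_numpy(), res.x, atol=1e-6)
    assert fit.llf == pytest.approx(-res.fun, abs=1e-6)


def test_conditional_logit_matches_statsmodels():
    from statsmodels.discrete.conditional_models import ConditionalLogit
    design = random_design(n_strata=80, J=4, seed=14, beta=[1.0, -1.0])
    fit = fit_conditional_logit(design)
    X, y, strata = design.matrices()
    sm_fit = ConditionalLogit(y, X, groups=strata).fit(disp=0)
    np.testing.assert_allclose(fit.params.to_numpy(), sm_fit.params,
                               atol=1e-4)
    np.testing.assert_allclose(fit.bse.to_numpy(), sm_fit.bse, rtol=1e-3)


def test_stratum_constant_shift_invariance():
    design = random_design(seed=15, beta=[0.5, 0.5])
    fit1 = fit_conditional_logit(design)
    shifted = design.rows.copy()
    shifts = {s: v for s, v in zip(
        shifted["stratum_id"].unique(),
        np.random.default_rng(16).standard_normal(
            shifted["stratum_id"].nunique()))}
    shifted["c0"] = shifted["c0"] + shifted["stratum_id"].map(shifts)
    fit2 = fit_conditional_logit(StepDesign(shifted, design.J,
                                            design.formula))
    np.testing.assert_allclose(fit1.params.to_numpy(),
                               fit2.params.to_numpy(), atol=1e-7)
    assert fit1.llf == pytest.approx(fit2.llf, abs=1e-7)


def test_rescaling_equivariance():
    design = random_design(seed=17, beta=[0.7, -0.3])
    fit1 = fit_conditional_logit(design)
    doubled = design.rows.copy()
    doubled["c0"] = 2.0 * doubled["c0"]
    fit2 = fit_conditional_logit(StepDesign(doubled, design.J,
                                            design.formula))
    assert fit2.params["c0"] == pytest.approx(fit1.params["c0"] / 2,
                                              abs=1e-7)
    assert fit2.params["c1"] == pytest.approx(fit1.params["c1"], abs=1e-7)


def test_separation_is_diagnosed():
    rows = []
    rng = np.random.default_rng(18)
    for s in range(20):
        vals = rng.standard_normal(3)
        used_val = vals.max() + 1.0
        allv = [used_val, *vals]
        for r, v in enumerate(allv):
            rows.append(dict(animal_id="A", stratum_id=s, case=int(r == 0),
                             x1=0, y1=0, x2=0, y2=0, sl=1.0, ta=0.0, c0=v))
    design = StepDesign(pd.DataFrame(rows), J=3, formula=["c0"])
    fit = fit_conditional_logit(design)
    assert not fit.converged
    assert "c0" in fit.diagnostics.get("separation", [])


# ------------------------------------------------------------ Poisson trick

def test_poisson_trick_slopes_match_conditional_logit():
    design = random_design(n_strata=60, J=3, seed=19, beta=[0.6, -0.9])
    f1 = fit_conditional_logit(design)
    f2 = fit_poisson_trick(design)
    np.testing.assert_allclose(f1.params.to_numpy(), f2.params.to_numpy(),
                               atol=1e-6)
    np.testing.assert_allclose(f1.bse.to_numpy(), f2.bse.to_numpy(),
                               atol=1e-6)


def test_poisson_single_stratum_normalizer():
    design = random_design(n_strata=1, J=4, seed=20)
    X, y, strata = design.matrices()
    beta = np.array([0.3, -0.2])
    eta = X @ beta
    # profiled intercept must equal minus the softmax normalizer
    from habsel.issa import _segment_logsumexp
    lse, _ = _segment_logsumexp(eta, strata, 1)
    mu = np.exp(-lse[strata] + eta)
    assert mu.sum() == pytest.approx(1.0)


def test_loglik_offset_is_constant_in_beta():
    design = random_design(n_strata=10, J=3, seed=21)
    X, y, strata = design.matrices()
    from habsel.issa import _clogit_parts, _segment_logsumexp
    rng = np.random.default_rng(22)
    offsets = []
    for _ in range(5):
        beta = rng.standard_normal(2)
        ll_c, _, _ = _clogit_parts(beta, X, y, strata, 10)
        eta = X @ beta
        lse, _ = _segment_logsumexp(eta, strata, 10)
        alpha = -lse
        mu = np.exp(alpha[strata] + eta)
        ll_p = float(np.sum(y * (alpha[strata] + eta)) - mu.sum())
        offsets.append(ll_p - ll_c)
    np.testing.assert_allclose(offsets, -10.0, atol=1e-10)


def test_availability_sample_stability_j10_vs_j50(zstack, small_cohort):
    """Increasing J from 10 to 50 moves estimates by less than 1 SE."""
    tracks, _ = small_cohort
    used = []
    for t in tracks:
        used.extend(clean_and_build_steps(t))
    kern = fit_movement_kernel(used)
    cols = ["forest_edge_density", "development_cover@150",
            "log_sl", "cos_ta"]
    fits = []
    for J in (10, 50):
        d = sample_available(used, kern, zstack.extent, J=J, seed=23)
        d = extract_step_covariates(
            d, zstack, [("forest_edge_density", None),
                        ("development_cover", 150)])
        fits.append(fit_conditional_logit(d, cols))
    for c in cols[:2]:
        assert abs(fits[0].params[c] - fits[1].params[c]) < fits[0].bse[c]


# ------------------------------------------------------------- properties

from hypothesis import given, settings
from hypothesis import strategies as st

from habsel.issa import _wrap_angle


@settings(deadline=None, max_examples=200)
@given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
def test_wrap_angle_range_and_congruence(a):
    w = float(_wrap_angle(a))
    assert -np.pi < w <= np.pi
    assert np.cos(w) == pytest.approx(np.cos(a), abs=1e-6)
    assert np.sin(w) == pytest.approx(np.sin(a), abs=1e-6)
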