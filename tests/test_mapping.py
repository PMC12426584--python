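"""Suitability surfaces, tercile classification, bivariate overlay,
class summaries, and the conflict GLM."""

import numpy as np
import pandas as pd
import pytest

import habsel as hs
from habsel.core import FitResult, IncidentSet
from habsel.landscape import CovariateStack, RasterGrid
from habsel.mapping import (bivariate_overlap, fit_conflict_glm,
                            predict_surface, rescale_sd, sample_background,
                            summarize_classes, tercile_classify)
from habsel.selection import ModelSpec


def fit_with(params):
    idx = pd.Index(list(params))
    return FitResult(pd.Series(params), pd.Series(0.1, index=idx), 0.0,
                     100, "logistic_rsf", True)


def simple_stack(field, name="f", res=30.0):
    g = RasterGrid(np.asarray(field, dtype=float), res, name=name)
    return CovariateStack(layers={name: g})


# ---------------------------------------------------------------- predict

def test_zero_beta_gives_unit_surface():
    stack = simple_stack(np.random.default_rng(0).random((10, 10)))
    surf = predict_surface(stack, fit_with({"f": 0.0}),
                           ModelSpec("movement", ("f",)))
    np.testing.assert_allclose(surf.w.values, 1.0)


def test_identity_exponentiation():
    vals = np.log(np.arange(1, 26, dtype=float).reshape(5, 5))
    stack = simple_stack(vals)
    surf = predict_surface(stack, fit_with({"f": 1.0}),
                           ModelSpec("movement", ("f",)))
    np.testing.assert_allclose(surf.w.values, np.exp(vals))


def test_bilinearity_of_linear_predictor():
    rng = np.random.default_rng(1)
    vals = rng.random((8, 8))
    s1 = predict_surface(simple_stack(vals), fit_with({"f": 2.0}),
                         ModelSpec("movement", ("f",)))
    s2 = predict_surface(simple_stack(vals / 2), fit_with({"f": 4.0}),
                         ModelSpec("movement", ("f",)))
    np.testing.assert_allclose(s1.eta.values, s2.eta.values)


def test_movement_terms_and_intercept_excluded():
    stack = simple_stack(np.ones((4, 4)))
    fit = fit_with({"f": 1.0, "log_sl": 5.0, "cos_ta": -3.0,
                    "intercept": 9.0})
    surf = predict_surface(stack, fit,
                           ModelSpec("movement",
                                     ("f", "log_sl", "cos_ta", "intercept")))
    np.testing.assert_allclose(surf.eta.values, 1.0)


def test_missing_layer_is_named():
    stack = simple_stack(np.ones((4, 4)))
    with pytest.raises(KeyError, match="ghost"):
        predict_surface(stack, fit_with({"ghost": 1.0}),
                        ModelSpec("movement", ("ghost",)))


# ---------------------------------------------------------------- rescale

def test_rescale_mean_zero_sd_one():
    rng = np.random.default_rng(2)
    stack = simple_stack(rng.random((50, 50)))
    surf = rescale_sd(predict_surface(stack, fit_with({"f": 3.0}),
                                      ModelSpec("movement", ("f",))))
    assert abs(surf.rescaled.values.mean()) < 1e-12
    assert abs(surf.rescaled.values.std() - 1.0) < 1e-12


def test_rescale_affine_invariance():
    rng = np.random.default_rng(3)
    vals = rng.random((20, 20))
    a = rescale_sd(predict_surface(simple_stack(vals), fit_with({"f": 1.0}),
                                   ModelSpec("movement", ("f",))))
    b = rescale_sd(predict_surface(simple_stack(5.0 * vals + 2.0),
                                   fit_with({"f": 1.0}),
                                   ModelSpec("movement", ("f",))))
    np.testing.assert_allclose(a.rescaled.values, b.rescaled.values,
                               atol=1e-10)


def test_rescale_constant_surface_rejected():
    surf = predict_surface(simple_stack(np.ones((5, 5))),
                           fit_with({"f": 1.0}),
                           ModelSpec("movement", ("f",)))
    with pytest.raises(ValueError, match="variance"):
        rescale_sd(surf)


# --------------------------------------------------------------- terciles

def test_tercile_shares_on_tie_free_raster():
    rng = np.random.default_rng(4)
    g = RasterGrid(rng.random((300, 300)), 30.0, name="w")
    classes = tercile_classify(g)
    for c in (0, 1, 2):
        share = np.mean(classes.values == c)
        assert 0.330 <= share <= 0.337


def test_tercile_constant_raster_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        classes = tercile_classify(RasterGrid(np.ones((10, 10)), 30.0,
                                              name="w"))
    assert len(np.unique(classes.values)) == 1


def test_tercile_monotone_transform_invariance():
    rng = np.random.default_rng(5)
    vals = rng.random((40, 40)) + 0.5
    a = tercile_classify(RasterGrid(vals, 30.0, name="w"))
    b = tercile_classify(RasterGrid(np.log(vals), 30.0, name="logw"))
    np.testing.assert_array_equal(a.values, b.values)


# ---------------------------------------------------------------- overlay

def test_self_overlay_diagonal():
    rng = np.random.default_rng(6)
    g = tercile_classify(RasterGrid(rng.random((60, 60)), 30.0, name="w"))
    biv = bivariate_overlap(g, g)
    assert biv.conditional_shares["feed_high_given_move_high"] == 100.0
    assert biv.conditional_shares["move_high_given_feed_high"] == 100.0
    hh = biv.table[(biv.table.move_class == "high")
                   & (biv.table.feed_class == "high")]["pct"].iloc[0]
    high_marginal = 100.0 * np.mean(g.values == 2)
    assert hh == pytest.approx(high_marginal)


def test_independent_rasters_product_share():
    rng = np.random.default_rng(7)
    a = tercile_classify(RasterGrid(rng.random((300, 300)), 30.0, name="a"))
    b = tercile_classify(RasterGrid(rng.random((300, 300)), 30.0, name="b"))
    biv = bivariate_overlap(a, b)
    assert biv.high_high_pct == pytest.approx(100 / 9, abs=2.0)


def test_overlay_partitions_study_area():
    rng = np.random.default_rng(8)
    a = tercile_classify(RasterGrid(rng.random((50, 50)), 30.0, name="a"))
    b = tercile_classify(RasterGrid(rng.random((50, 50)), 30.0, name="b"))
    biv = bivariate_overlap(a, b)
    assert biv.table["cells"].sum() == 2500
    assert biv.table["pct"].sum() == pytest.approx(100.0)


def test_overlay_misaligned_rejected():
    a = tercile_classify(RasterGrid(np.random.rand(10, 10), 30.0, name="a"))
    b = tercile_classify(RasterGrid(np.random.rand(11, 11), 30.0, name="b"))
    with pytest.raises(ValueError, match="aligned"):
        bivariate_overlap(a, b)


# --------------------------------------------------------------- summaries

def test_summaries_constant_class(stack):
    ref = stack.reference
    move = ref.like(np.zeros(ref.shape), "m")    # all "low"
    feed = ref.like(np.full(ref.shape, 2.0), "f")
    biv = bivariate_overlap(move, feed)
    const = CovariateStack(layers={
        "dev": ref.like(np.full(ref.shape, 40.0), "dev")})
    tab = summarize_classes(biv, const, [("low", "high")], ["dev"],
                            n_points=1000, seed=9)
    assert tab["mean"].iloc[0] == pytest.approx(40.0)
    assert tab["sd"].iloc[0] == pytest.approx(0.0)
    assert tab["n"].iloc[0] == 1000


def test_summaries_match_exhaustive_mean(stack):
    rng = np.random.default_rng(10)
    ref = stack.reference
    w = rng.random(ref.shape)
    classes = tercile_classify(ref.like(w, "w"))
    biv = bivariate_overlap(classes, classes)
    cov = ref.like(rng.random(ref.shape) * 100, "cov")
    cstack = CovariateStack(layers={"cov": cov})
    tab = summarize_classes(biv, cstack, [("high", "high")], ["cov"],
                            n_points=1000, seed=11)
    exact = cov.values[classes.values == 2].mean()
    tol = 2 * tab["sd"].iloc[0] / np.sqrt(1000)
    assert abs(tab["mean"].iloc[0] - exact) < 2 * tol + 1.0


def test_summaries_empty_class_skipped(stack):
    ref = stack.reference
    move = ref.like(np.zeros(ref.shape), "m")
    feed = ref.like(np.zeros(ref.shape), "f")
    biv = bivariate_overlap(move, feed)
    with pytest.warns(UserWarning, match="empty"):
        tab = summarize_classes(biv, stack, [("high", "high")], ["slope"],
                                n_points=10, seed=12)
    assert tab.empty


# ------------------------------------------------------------ conflict GLM

def surfaces_for_conflict(seed=13, shape=(80, 80)):
    rng = np.random.default_rng(seed)
    sm = simple_stack(rng.random(shape), name="a")
    sf = simple_stack(rng.random(shape), name="b")
    move = rescale_sd(predict_surface(sm, fit_with({"a": 1.0}),
                                      ModelSpec("movement", ("a",))))
    feed = rescale_sd(predict_surface(sf, fit_with({"b": 1.0}),
                                      ModelSpec("feeding", ("b",))))
    return move, feed


def test_conflict_null_slopes_near_zero():
    move, feed = surfaces_for_conflict()
    rng = np.random.default_rng(14)
    xmin, ymin, xmax, ymax = move.w.extent
    inc = IncidentSet(pd.DataFrame({
        "x": rng.uniform(xmin, xmax, 300),
        "y": rng.uniform(ymin, ymax, 300), "type": "livestock"}))
    bg = sample_background(move.w.extent, 3000, seed=15)
    fit = fit_conflict_glm(inc, bg, move, feed)
    assert abs(fit.params["feed"]) < 2 * fit.bse["feed"]
    assert abs(fit.params["move"]) < 2 * fit.bse["move"]


def test_conflict_swap_symmetry():
    move, feed = surfaces_for_conflict(seed=16)
    inc = hs.simulate_incidents(move.rescaled, feed.rescaled,
                                (-5.0, 1.0, -1.0), 200, seed=17)
    bg = sample_background(move.w.extent, 2000, seed=18)
    f1 = fit_conflict_glm(inc, bg, move, feed)
    f2 = fit_conflict_glm(inc, bg, feed, move)
    assert f1.params["feed"] == pytest.approx(f2.params["move"], abs=1e-9)
    assert f1.params["move"] == pytest.approx(f2.params["feed"], abs=1e-9)


def test_conflict_recovery_single_replicate():
    move, feed = surfaces_for_conflict(seed=19, shape=(120, 120))
    inc = hs.simulate_incidents(move.rescaled, feed.rescaled,
                                (-6.0, 1.0, -1.0), 500, seed=20)
    bg = sample_background(move.w.extent, 5000, seed=21)
    fit = fit_conflict_glm(inc, bg, move, feed)
    assert fit.params["feed"] > 0 and fit.params["move"] < 0
    assert abs(fit.params["feed"] - 1.0) < 2 * fit.bse["feed"]
    assert abs(fit.params["move"] + 1.0) < 2 * fit.bse["move"]


def test_conflict_requires_rescaled_surfaces():
    sm = simple_stack(np.random.rand(10, 10), name="a")
    move = predict_surface(sm, fit_with({"a": 1.0}),
                           ModelSpec("movement", ("a",)))
    feed = rescale_sd(predict_surface(sm, fit_with({"a": 2.0}),
                                      ModelSpec("feeding", ("a",))))
    inc = IncidentSet(pd.DataFrame({"x": [10.0], "y": [10.0],
                                    "type": "sighting"}))
    with pytest.raises(ValueError, match="rescaled"):
        fit_conflict_glm(inc, sample_background(move.w.extent, 10, 1),
                         move, feed)
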