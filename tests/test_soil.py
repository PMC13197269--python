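"""Penalized-spline smooth, derivative CIs and the breakpoint rule."""

import numpy as np
import pandas as pd
import pytest

import stemwater as sw
from stemwater.soil import SoilSeries, fit_smooth

# Oracle values from an independent REML GAM implementation (R mgcv,
# gam(y ~ s(x, bs="bs", k=6, m=c(3,2)), method="REML")) on the fixture
# generated below.  Frozen from that run.
MGCV_PRED = [0.7061, 0.6618, 0.7023, 0.7861, 0.8732, 0.9433,
             0.9881, 0.9998, 0.9849, 0.9714, 0.9896]
MGCV_EDF = 5.8959
MGCV_SIG2 = 0.0013825


def sigmoid_fixture():
    rng = np.random.default_rng(1234)
    x = rng.uniform(0.12, 0.32, 300)
    y = 1 / (1 + np.exp(-(x - 0.19) / 0.01)) * 0.3 + 0.68 + rng.normal(0, 0.03, 300)
    return pd.DataFrame({"soil_vwc": x, "stem_rwc": y})


def test_fit_smooth_matches_independent_reml_implementation():
    pairs = sigmoid_fixture()
    fit = fit_smooth(pairs, k=6)
    grid = np.linspace(pairs.soil_vwc.min(), pairs.soil_vwc.max(), 11)
    assert fit.predict(grid) == pytest.approx(MGCV_PRED, abs=5e-4)
    assert fit.edf == pytest.approx(MGCV_EDF, abs=0.01)
    assert fit.sigma2 == pytest.approx(MGCV_SIG2, rel=0.01)


def test_penalty_shrinks_noiseless_line_to_linear_fit():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, 200)
    y = 2.0 + 3.0 * x + rng.normal(0, 1e-4, 200)
    fit = fit_smooth(pd.DataFrame({"soil_vwc": x, "stem_rwc": y}), k=6)
    grid = np.linspace(0, 1, 50)
    assert np.allclose(fit.predict(grid), 2.0 + 3.0 * grid, atol=0.02)
    assert fit.edf < 2.5  # effective degrees of freedom near a straight line


def test_noiseless_sine_fits_well_with_k6():
    x = np.linspace(0, 1, 300)
    y = np.sin(2 * np.pi * x * 0.75)
    fit = fit_smooth(pd.DataFrame({"soil_vwc": x, "stem_rwc": y}), k=6)
    rmse = np.sqrt(np.mean((fit.predict(x) - y) ** 2))
    assert rmse < 0.05  # amplitude 1


def test_fit_smooth_requires_enough_distinct_x():
    pairs = pd.DataFrame({"soil_vwc": [0.1, 0.1, 0.2, 0.2] * 5, "stem_rwc": 1.0})
    with pytest.raises(ValueError, match="distinct"):
        fit_smooth(pairs, k=6)


def test_derivative_matches_slope_for_linear_trend():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, 200)
    y = 1.0 - 0.4 * x + rng.normal(0, 1e-4, 200)
    fit = fit_smooth(pd.DataFrame({"soil_vwc": x, "stem_rwc": y}), k=6)
    grid = sw.derivative_with_ci(fit, n_grid=50, seed=0)
    assert np.allclose(grid["derivative"], -0.4, atol=5e-3)
    drying = sw.derivative_with_ci(fit, n_grid=50, seed=0, drying=True)
    assert np.allclose(drying["derivative"], 0.4, atol=5e-3)
    assert np.all(drying["ci_lower"] <= drying["derivative"])
    assert np.all(drying["derivative"] <= drying["ci_upper"])


def test_derivative_integrates_back_to_curve():
    pairs = sigmoid_fixture()
    fit = fit_smooth(pairs, k=6)
    a, b = fit.x_min, fit.x_max
    xs = np.linspace(a, b, 4001)
    deriv = sw.derivative_with_ci(fit, n_grid=4001, seed=0)["derivative"].to_numpy()
    integral = np.trapezoid(deriv, xs)
    assert integral == pytest.approx(
        fit.predict(b) - fit.predict(a), rel=1e-6, abs=1e-8
    )


def test_derivative_ci_deterministic_given_seed():
    pairs = sigmoid_fixture()
    fit = fit_smooth(pairs, k=6)
    g1 = sw.derivative_with_ci(fit, seed=11)
    g2 = sw.derivative_with_ci(fit, seed=11)
    pd.testing.assert_frame_equal(g1, g2)


def grid_from(vwc, deriv, hi):
    return pd.DataFrame(
        {
            "soil_vwc": vwc,
            "derivative": deriv,
            "ci_lower": np.asarray(deriv) - 0.1,
            "ci_upper": hi,
        }
    )


def test_detect_threshold_none_when_all_derivatives_positive():
    vwc = np.linspace(0.1, 0.3, 40)
    grid = grid_from(vwc, np.full(40, 0.5), np.full(40, 0.7))
    assert sw.detect_threshold(grid).threshold_vwc is None


def test_detect_threshold_finds_constructed_run_at_0p19():
    # qualifying (CI<0 and strongest-negative-quartile) exactly on the five
    # grid points from 0.19 downward
    vwc = np.round(np.arange(0.15, 0.31, 0.01), 2)  # 16 points
    deriv = np.where(vwc <= 0.19, -5.0, 0.1)  # 5 strongly negative points
    hi = np.where(vwc <= 0.19, -1.0, 0.2)
    res = sw.detect_threshold(grid_from(vwc, deriv, hi))
    assert res.threshold_vwc == pytest.approx(0.19)
    trace = res.criteria_trace
    assert trace["qualifying"].sum() == 5
    assert bool(trace.loc[trace.soil_vwc == 0.19, "qualifying"].iloc[0])


def test_detect_threshold_rejects_four_point_run():
    vwc = np.round(np.arange(0.15, 0.31, 0.01), 2)
    deriv = np.where((vwc >= 0.16) & (vwc <= 0.19), -5.0, 0.1)  # only 4 points
    hi = np.where((vwc >= 0.16) & (vwc <= 0.19), -1.0, 0.2)
    assert sw.detect_threshold(grid_from(vwc, deriv, hi)).threshold_vwc is None


def test_detect_threshold_requires_both_criteria():
    # every point is "significant" (CI < 0) but the strongest-quartile
    # points are scattered, never 5 in a row → the rule must not fire
    vwc = np.linspace(0.1, 0.3, 40)
    deriv = np.full(40, -1.0)
    deriv[::3] = -5.0  # isolated strong declines
    hi = np.full(40, -0.01)
    res = sw.detect_threshold(grid_from(vwc, deriv, hi))
    assert res.criteria_trace["ci_below_zero"].all()
    assert res.threshold_vwc is None


def test_detect_threshold_invariant_to_affine_response_rescaling():
    vwc = np.linspace(0.12, 0.32, 60)
    rng = np.random.default_rng(2)
    deriv = np.where(vwc < 0.2, -3.0, 0.05) + rng.normal(0, 0.01, 60)
    hi = deriv + 0.5
    base = sw.detect_threshold(grid_from(vwc, deriv, hi))
    scaled = sw.detect_threshold(grid_from(vwc, 3.7 * deriv, 3.7 * hi))
    assert base.threshold_vwc == scaled.threshold_vwc


def test_daily_pairs_join_and_drop():
    idx = pd.date_range("2023-07-01", periods=3 * 24, freq="1h")
    soil = SoilSeries(
        pd.DataFrame({"100cm": 0.25}, index=idx), reference_max=0.2923
    )
    stem = pd.DataFrame(
        {
            "tree_id": ["a", "a", "a", "b"],
            "rwc_day_max": [1.0, 0.9, 0.8, 0.95],
        },
        index=pd.Index(
            list(pd.date_range("2023-07-01", periods=3).date)
            + [pd.Timestamp("2023-08-01").date()],  # no soil data that day
            name="date",
        ),
    )
    pairs = sw.daily_pairs(stem, soil, "100cm", groups={"a": "palm", "b": "dicot"})
    assert len(pairs) == 3
    assert set(pairs["group"]) == {"palm"}
    with pytest.raises(KeyError):
        sw.daily_pairs(stem, soil, "400cm")


def test_daily_pairs_rejects_disjoint_ranges():
    idx = pd.date_range("2023-07-01", periods=24, freq="1h")
    soil = SoilSeries(pd.DataFrame({"100cm": 0.25}, index=idx), reference_max=0.29)
    stem = pd.DataFrame(
        {"tree_id": ["a"], "rwc_day_max": [1.0]},
        index=pd.Index([pd.Timestamp("2024-01-01").date()], name="date"),
    )
    with pytest.raises(ValueError, match="overlap"):
        sw.daily_pairs(stem, soil, "100cm")


def test_compare_groups_zero_statistic_for_identical_groups():
    pairs = sigmoid_fixture()
    half = pairs.copy()
    half["group"] = "palm"
    other = pairs.copy()
    other["group"] = "dicot"
    both = pd.concat([half, other], ignore_index=True)
    fp = fit_smooth(both, "palm", k=6)
    fd = fit_smooth(both, "dicot", k=6)
    F, p = sw.compare_groups(fp, fd, both, k=6)
    assert F == pytest.approx(0.0, abs=1e-6)
    assert p > 0.99


def test_compare_groups_detects_grossly_different_curves():
    rng = np.random.default_rng(9)
    x = rng.uniform(0.1, 0.3, 250)
    palm = pd.DataFrame(
        {
            "soil_vwc": x,
            "stem_rwc": 1 / (1 + np.exp(-(x - 0.19) / 0.008)) * 0.35
            + 0.65
            + rng.normal(0, 0.02, 250),
            "group": "palm",
        }
    )
    dicot = pd.DataFrame(
        {
            "soil_vwc": x,
            "stem_rwc": 0.8 + 0.5 * x + rng.normal(0, 0.02, 250),
            "group": "dicot",
        }
    )
    both = pd.concat([palm, dicot], ignore_index=True)
    F, p = sw.compare_groups(
        fit_smooth(both, "palm", k=6), fit_smooth(both, "dicot", k=6), both, k=6
    )
    assert p < 0.001


def test_compare_groups_null_rarely_significant():
    """Groups drawn from one curve: α=0.05 rejections in ≤ ~10% of seeds."""
    rejections = 0
    n_rep = 20
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 0.3, 200)
        y = 0.7 + 1.2 * x + rng.normal(0, 0.03, 200)
        df = pd.DataFrame({"soil_vwc": x, "stem_rwc": y})
        df["group"] = np.where(rng.random(200) < 0.5, "palm", "dicot")
        F, p = sw.compare_groups(
            fit_smooth(df, "palm", k=6), fit_smooth(df, "dicot", k=6), df, k=6
        )
        rejections += p < 0.05
    assert rejections <= max(2, int(0.1 * n_rep) + 1)
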