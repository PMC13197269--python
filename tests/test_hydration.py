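"""Percentile convention, daily summaries, storage metrics and geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import stemwater as sw
from stemwater.hydration import sapwood_depth_from_dbh

from conftest import make_sensor


@pytest.mark.parametrize(
    "values, p, expected",
    [
        ([1, 2, 3, 4, 5], 50, 3.0),
        (list(range(1, 101)), 99, 99.01),  # linear interpolation convention
        ([7.0] * 10, 1, 7.0),
        ([7.0] * 10, 99, 7.0),
    ],
)
def test_percentile_convention(values, p, expected):
    assert sw.percentile(values, p) == pytest.approx(expected, abs=1e-12)


def test_percentile_rejects_empty_input():
    with pytest.raises(ValueError):
        sw.percentile([], 50)
    with pytest.raises(ValueError):
        sw.percentile([np.nan], 50)


def test_summarise_days_constant_series(constant_series):
    days = sw.summarise_days(constant_series, theta_turgid=0.5)
    assert len(days) == 5
    assert np.allclose(days["daily_range"], 0.0)
    assert np.allclose(days["rwc_day_max"], 1.0)


def test_summarise_days_sinusoid_range_close_to_twice_amplitude():
    idx = pd.date_range("2023-07-01", periods=96, freq="15min")
    hours = idx.hour + idx.minute / 60
    a = 0.03
    theta = 0.5 + a * np.sin(2 * np.pi * hours / 24)
    cal = sw.CalibratedSeries("s", pd.Series(theta, index=idx, name="theta"))
    days = sw.summarise_days(cal, theta_turgid=0.53)
    # brute-force oracle: within-day 99th − 1st percentile of the samples
    brute = np.percentile(theta, 99) - np.percentile(theta, 1)
    assert days["daily_range"].iloc[0] == pytest.approx(brute, rel=1e-12)
    assert days["daily_range"].iloc[0] == pytest.approx(2 * a, rel=0.02)


def test_summarise_days_excludes_sparse_days(constant_series):
    theta = constant_series.theta.copy()
    theta.iloc[10:96] = np.nan  # day 1 keeps only 10 of 96 samples
    cal = sw.CalibratedSeries("s", theta)
    days = sw.summarise_days(cal, theta_turgid=0.5)
    assert len(days) == 4


def test_summarise_days_rejects_nonpositive_turgid(constant_series):
    with pytest.raises(ValueError):
        sw.summarise_days(constant_series, theta_turgid=0.0)


def test_storage_metrics_formulas_on_constructed_series():
    rng = np.random.default_rng(5)
    theta = rng.uniform(0.4, 0.7, 10 * 96)
    s = make_sensor(theta, 25.0)
    cal = sw.calibrate_series(s)
    days = sw.summarise_days(cal, sw.percentile(theta, 99))
    m = sw.storage_metrics(cal, days)
    assert m.theta_turgid == pytest.approx(np.percentile(theta, 99), abs=1e-9)
    assert m.theta_dry == pytest.approx(np.percentile(theta, 1), abs=1e-9)
    assert m.seasonal_delta == pytest.approx(m.theta_turgid - m.theta_dry)
    assert m.water_deficit_pct == pytest.approx(
        100 * (m.theta_turgid - m.theta_dry) / m.theta_turgid
    )
    assert m.cv_pct == pytest.approx(100 * m.theta_sd / m.theta_mean)
    assert m.theta_dry <= m.theta_mean <= m.theta_turgid


def test_constant_series_has_zero_deltas(constant_series):
    days = sw.summarise_days(constant_series, 0.5)
    m = sw.storage_metrics(constant_series, days)
    assert m.seasonal_delta == 0.0
    assert m.diurnal_delta == 0.0
    assert m.water_deficit_pct == 0.0


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_diurnal_delta_below_seasonal_delta_for_smooth_series(seed):
    """For physically plausible series (smooth diurnal cycle on a seasonal
    trend, small sensor noise) the maximum daily range stays within the
    full-series range.  This does NOT hold for arbitrary heavy-noise series:
    a single day's 99th percentile trims fewer points than the full-series
    one, so iid noise can invert the order.
    """
    rng = np.random.default_rng(seed)
    n_days = 5
    t = np.arange(n_days * 96) / 96
    amp = rng.uniform(0.005, 0.04)
    trend = rng.uniform(0.05, 0.2)
    theta = 0.6 - trend * t / n_days - amp * np.sin(2 * np.pi * t) ** 2
    theta += rng.normal(0, 2e-4, len(t))
    idx = pd.date_range("2023-07-01", periods=len(theta), freq="15min")
    cal = sw.CalibratedSeries("s", pd.Series(theta, index=idx, name="theta"))
    days = sw.summarise_days(cal, sw.percentile(theta, 99))
    m = sw.storage_metrics(cal, days)
    assert m.diurnal_delta <= m.seasonal_delta + 1e-12


def test_sapwood_area_annulus_hand_value():
    assert sw.sapwood_area(0.22, 0.035) == pytest.approx(0.02034, abs=5e-5)


def test_sapwood_area_limits():
    full = math.pi * 0.11**2
    assert sw.sapwood_area(0.22, 0.11 - 1e-9) == pytest.approx(full, rel=1e-6)
    assert sw.sapwood_area(0.22, 1e-9) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        sw.sapwood_area(0.22, 0.11)


def test_active_storage_palm_cylinder():
    palm = sw.TreeSpec("p", "palm", height=13.0, dbh=0.22)
    assert sw.active_storage(palm, 0.728) == pytest.approx(0.36, abs=0.005)
    assert sw.active_storage(palm, 0.0) == 0.0


def test_active_storage_dicot_tapered_sapwood():
    dicot = sw.TreeSpec("d", "dicot", height=20.0, dbh=0.22, sapwood_depth=0.035)
    # f · A_s · H · θ = 0.5 · 0.02034 · 20 · 0.423 ≈ 0.086 m³
    assert sw.active_storage(dicot, 0.423) == pytest.approx(0.086, abs=0.001)


def test_active_storage_linear_in_theta_and_height():
    palm = sw.TreeSpec("p", "palm", height=10.0, dbh=0.3)
    tall = sw.TreeSpec("p", "palm", height=20.0, dbh=0.3)
    assert sw.active_storage(palm, 0.6) == pytest.approx(2 * sw.active_storage(palm, 0.3))
    assert sw.active_storage(tall, 0.6) == pytest.approx(2 * sw.active_storage(palm, 0.6))


def test_active_storage_uses_allometry_when_depth_missing():
    dicot = sw.TreeSpec("d", "dicot", height=20.0, dbh=0.22)
    expected_depth = sapwood_depth_from_dbh(0.22)
    assert expected_depth == pytest.approx(0.035, abs=1e-9)
    manual = sw.TreeSpec("d", "dicot", height=20.0, dbh=0.22, sapwood_depth=expected_depth)
    assert sw.active_storage(dicot, 0.4) == pytest.approx(sw.active_storage(manual, 0.4))


def test_active_storage_names_missing_geometry():
    with pytest.raises(ValueError, match="height"):
        sw.active_storage(sw.TreeSpec("p", "palm", dbh=0.22), 0.5)
    with pytest.raises(ValueError, match="dbh"):
        sw.active_storage(sw.TreeSpec("p", "palm", height=10.0), 0.5)


@pytest.mark.parametrize(
    "vwc, ref, expected",
    [(0.2923, 0.2923, 1.0), (0.19, 0.2923, 0.65), (0.0, 0.2923, 0.0)],
)
def test_relative_soil_water(vwc, ref, expected):
    assert sw.relative_soil_water(vwc, ref) == pytest.approx(expected, abs=0.002)


def test_relative_soil_water_rejects_nonpositive_reference():
    with pytest.raises(ValueError):
        sw.relative_soil_water(0.2, 0.0)


def test_tree_spec_validation():
    with pytest.raises(ValueError):
        sw.TreeSpec("x", "shrub")
    with pytest.raises(ValueError):
        sw.TreeSpec("x", "dicot", dbh=0.2, sapwood_depth=0.15)
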