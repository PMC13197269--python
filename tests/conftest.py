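import numpy as np
import pandas as pd
import pytest

import stemwater as sw


@pytest.fixture(scope="session")
def scenario():
    """One default 163-day scenario, shared across tests (seed 42)."""
    return sw.generate_scenario(sw.ScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def scenario_tables(scenario):
    """Calibrated daily summaries and storage metrics for every tree."""
    out = {}
    for sensor, truth in zip(scenario.sensors, scenario.truths):
        cal = sw.calibrate_series(sensor)
        theta_t = sw.percentile(cal.theta.dropna().to_numpy(), 99.0)
        days = sw.summarise_days(cal, theta_t)
        metrics = sw.storage_metrics(cal, days)
        out[sensor.tree_id] = {
            "cal": cal,
            "days": days,
            "metrics": metrics,
            "truth": truth,
        }
    return out


@pytest.fixture(scope="session")
def reference_table():
    from stemwater.datasets import amazon_drydown

    return amazon_drydown()


@pytest.fixture()
def constant_series():
    """A flat 5-day calibrated series at θ = 0.5, 15-min cadence."""
    idx = pd.date_range("2023-07-01", periods=5 * 96, freq="15min")
    return sw.CalibratedSeries("flat", pd.Series(0.5, index=idx, name="theta"))


def make_sensor(theta, t_stem, tree_id="t1", start="2023-07-01", freq="15min"):
    """Sensor series whose calibrated output is exactly ``theta``."""
    theta = np.asarray(theta, float)
    t = np.broadcast_to(np.asarray(t_stem, float), theta.shape)
    idx = pd.date_range(start, periods=len(theta), freq=freq)
    eps = sw.invert_calibration(theta, t)
    return sw.SensorSeries(
        tree_id, pd.DataFrame({"epsilon": eps, "t_stem": t}, index=idx)
    )
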