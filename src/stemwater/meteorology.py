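"""Vapour pressure deficit and daily meteorological summaries.

Saturation vapour pressure uses the Tetens formula,
``esat(T) = 0.6108·exp(17.27·T / (T + 237.3))`` kPa, the standard
agrometeorological choice for near-surface air temperatures.  VPD is
``esat·(1 − RH/100)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .util import DAY_COMPLETENESS, percentile

__all__ = ["esat", "vpd", "daily_max_vpd"]


def esat(t_air):
    """Tetens saturation vapour pressure (kPa) at air temperature ``t_air`` °C."""
    t = np.asarray(t_air, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return out if out.ndim else float(out)


def vpd(t_air, rh):
    """Vapour pressure deficit (kPa) from air temperature (°C) and RH (%)."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr[np.isfinite(rh_arr)] < 0) | (rh_arr[np.isfinite(rh_arr)] > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    out = esat(t_air) * (1.0 - rh_arr / 100.0)
    return out if np.ndim(out) else float(out)


def daily_max_vpd(
    meteo: pd.DataFrame,
    p: float = 99.0,
    completeness: float = DAY_COMPLETENESS,
) -> pd.Series:
    """Per-day maximum (99th-percentile) VPD in kPa.

    ``meteo`` is timestamp-indexed with columns ``t_air`` and ``rh``.  Days
    with fewer than ``completeness`` of the expected samples are dropped with
    a warning; the percentile trims spikes relative to a hard maximum.
    """
    if not isinstance(meteo.index, pd.DatetimeIndex):
        raise TypeError("meteo requires a DatetimeIndex")
    series = pd.Series(
        vpd(meteo["t_air"].to_numpy(), meteo["rh"].to_numpy()), index=meteo.index
    )
    expected = _samples_per_day(meteo.index)
    out = {}
    dropped = []
    for date, vals in series.groupby(series.index.date):
        good = vals.dropna()
        if len(good) < completeness * expected:
            dropped.append(date)
            continue
        out[date] = percentile(good.to_numpy(), p)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} incomplete day(s): {dropped[:3]}...")
    res = pd.Series(out, name="vpd_max", dtype=float)
    res.index.name = "date"
    return res


def _samples_per_day(index: pd.DatetimeIndex) -> int:
    if len(index) < 2:
        return 1
    step = pd.Timedelta(index[1] - index[0])
    return max(1, int(pd.Timedelta(days=1) / step))
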