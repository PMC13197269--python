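"""Per-tree stem water storage statistics and active-storage volumes.

The descriptive vocabulary used throughout the package:

* θ_t, "turgid" water content — the seasonal 99th percentile of calibrated θ,
  taken as the fully hydrated reference of a tree.
* θ_d, "dry" water content — the seasonal 1st percentile.
* seasonal Δθ = θ_t − θ_d; water deficit % = (θ_t − θ_d)/θ_t · 100.
* diurnal Δθ — the 99th percentile of within-day ranges (each day's 99th
  minus 1st percentile), the maximum diurnal discharge capacity.
* RWC — relative water content, θ/θ_t (daily maximum RWC, reached at night,
  proxies a tree's hydration status).
* active storage S — water volume mobilisable from the stem: whole-stem
  cylinder for palms (no secondary growth, conduction through the whole
  parenchyma-rich stem), tapered sapwood volume for dicots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibratedSeries
from .util import DAY_COMPLETENESS, percentile

__all__ = [
    "TreeSpec",
    "StorageMetrics",
    "summarise_days",
    "storage_metrics",
    "sapwood_area",
    "sapwood_depth_from_dbh",
    "active_storage",
    "relative_soil_water",
    "DEFAULT_TAPERING_FACTOR",
    "DEFAULT_SAPWOOD_ALLOMETRY_SLOPE",
]

DEFAULT_TAPERING_FACTOR = 0.5
# Linear DBH → sapwood-depth allometry anchored at depth 3.5 cm for a
# 0.22 m DBH subcanopy tree; users with site-specific coefficients
# should override it.
DEFAULT_SAPWOOD_ALLOMETRY_SLOPE = 0.035 / 0.22


@dataclass(frozen=True)
class TreeSpec:
    """Identity and geometry of one monitored individual.

    ``group`` is ``"palm"`` or ``"dicot"``; heights in m, DBH in m, wood
    density in g cm⁻³, sapwood depth in m (dicots only; palms conduct
    through the whole stem).
    """

    tree_id: str
    group: Literal["palm", "dicot"]
    height: float | None = None
    dbh: float | None = None
    wood_density: float | None = None
    sapwood_depth: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("palm", "dicot"):
            raise ValueError(f"group must be 'palm' or 'dicot', got {self.group!r}")
        if self.height is not None and not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.dbh is not None and not self.dbh > 0:
            raise ValueError(f"dbh must be > 0, got {self.dbh}")
        if (
            self.sapwood_depth is not None
            and self.dbh is not None
            and not 0 < self.sapwood_depth < self.dbh / 2
        ):
            raise ValueError(
                f"sapwood_depth must lie in (0, dbh/2), got {self.sapwood_depth}"
            )


@dataclass(frozen=True)
class StorageMetrics:
    """Seasonal storage summary of one tree (the Table-1-style row)."""

    tree_id: str
    theta_turgid: float
    theta_dry: float
    theta_mean: float
    theta_sd: float
    cv_pct: float
    seasonal_delta: float
    diurnal_delta: float
    water_deficit_pct: float
    active_storage: float | None = None

    def __post_init__(self) -> None:
        if not self.theta_dry <= self.theta_mean <= self.theta_turgid:
            raise ValueError(
                f"{self.tree_id}: expected θ_d ≤ θ_mean ≤ θ_t, got "
                f"{self.theta_dry} / {self.theta_mean} / {self.theta_turgid}"
            )


def summarise_days(
    series: CalibratedSeries,
    theta_turgid: float,
    completeness: float = DAY_COMPLETENESS,
    p_hi: float = 99.0,
    p_lo: float = 1.0,
) -> pd.DataFrame:
    """Collapse a calibrated series to one row per calendar day.

    Returns columns ``theta_day_hi`` (within-day 99th percentile),
    ``theta_day_lo`` (1st), ``daily_range``, ``rwc_day_max`` (= hi/θ_t, not
    capped at 1) and ``n_samples``, indexed by date.  Days with fewer than
    ``completeness`` of the expected samples are excluded.  At 15-min cadence
    the within-day 99th percentile is effectively the nightly maximum.
    """
    if not theta_turgid > 0:
        raise ValueError(f"theta_turgid must be > 0, got {theta_turgid}")
    theta = series.theta
    expected = _samples_per_day(theta.index)
    rows = []
    for date, vals in theta.groupby(theta.index.date):
        good = vals.dropna()
        if len(good) < completeness * expected:
            continue
        hi = percentile(good.to_numpy(), p_hi)
        lo = percentile(good.to_numpy(), p_lo)
        rows.append(
            {
                "tree_id": series.tree_id,
                "date": date,
                "theta_day_hi": hi,
                "theta_day_lo": lo,
                "daily_range": hi - lo,
                "rwc_day_max": hi / theta_turgid,
                "n_samples": len(good),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tree_id",
            "date",
            "theta_day_hi",
            "theta_day_lo",
            "daily_range",
            "rwc_day_max",
            "n_samples",
        ],
    ).set_index("date")


def storage_metrics(
    series: CalibratedSeries,
    days: pd.DataFrame,
    p_hi: float = 99.0,
    p_lo: float = 1.0,
) -> StorageMetrics:
    """Seasonal storage statistics of one tree.

    θ_t / θ_d are the 99th / 1st percentiles of the full series; the diurnal
    Δθ is the 99th percentile of the per-day ranges in ``days`` (output of
    :func:`summarise_days`).  ``active_storage`` is left unset; attach it via
    :func:`active_storage` when geometry is known.
    """
    vals = series.theta.dropna().to_numpy()
    if vals.size == 0:
        raise ValueError(f"tree {series.tree_id!r}: empty series")
    theta_t = percentile(vals, p_hi)
    theta_d = percentile(vals, p_lo)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    diurnal = (
        percentile(days["daily_range"].to_numpy(), p_hi) if len(days) else float("nan")
    )
    return StorageMetrics(
        tree_id=series.tree_id,
        theta_turgid=theta_t,
        theta_dry=theta_d,
        theta_mean=mean,
        theta_sd=sd,
        cv_pct=100.0 * sd / mean,
        seasonal_delta=theta_t - theta_d,
        diurnal_delta=diurnal,
        water_deficit_pct=100.0 * (theta_t - theta_d) / theta_t,
    )


def sapwood_area(dbh: float, sapwood_depth: float) -> float:
    """Cross-sectional sapwood area (m²) as an annulus of the given depth."""
    if not dbh > 0:
        raise ValueError(f"dbh must be > 0, got {dbh}")
    if not 0 < sapwood_depth < dbh / 2:
        raise ValueError(
            f"sapwood_depth must lie in (0, dbh/2); got {sapwood_depth} for "
            f"dbh {dbh} — use whole-stem geometry instead"
        )
    r = dbh / 2
    return math.pi * (r**2 - (r - sapwood_depth) ** 2)


def sapwood_depth_from_dbh(
    dbh: float, slope: float = DEFAULT_SAPWOOD_ALLOMETRY_SLOPE, intercept: float = 0.0
) -> float:
    """Linear DBH → sapwood-depth allometry (m); coefficients user-settable."""
    return slope * dbh + intercept


def active_storage(
    tree: TreeSpec,
    theta: float,
    tapering_factor: float = DEFAULT_TAPERING_FACTOR,
    allometry_slope: float = DEFAULT_SAPWOOD_ALLOMETRY_SLOPE,
    allometry_intercept: float = 0.0,
) -> float:
    """Active stem water storage S (m³) at water content ``theta``.

    Palms: whole-stem cylinder, ``π·(dbh/2)²·height·θ``.  Dicots: tapered
    sapwood volume ``f·A_s·height·θ`` with tapering factor ``f`` (default
    0.5), using the measured sapwood depth when present, otherwise the
    linear DBH allometry.
    """
    for field_name in ("height", "dbh"):
        if getattr(tree, field_name) is None:
            raise ValueError(f"tree {tree.tree_id!r}: missing {field_name}")
    if tree.group == "palm":
        return math.pi * (tree.dbh / 2) ** 2 * tree.height * theta
    depth = tree.sapwood_depth
    if depth is None:
        depth = sapwood_depth_from_dbh(tree.dbh, allometry_slope, allometry_intercept)
    return tapering_factor * sapwood_area(tree.dbh, depth) * tree.height * theta


def relative_soil_water(vwc, reference_max: float):
    """Soil relative water content: VWC over a long-term 99th-percentile max."""
    if not reference_max > 0:
        raise ValueError(f"reference_max must be > 0, got {reference_max}")
    out = np.asarray(vwc, dtype=float) / reference_max
    return out if out.ndim else float(out)


def _samples_per_day(index: pd.DatetimeIndex) -> int:
    if len(index) < 2:
        return 1
    step = pd.Timedelta(index[1] - index[0])
    return max(1, int(pd.Timedelta(days=1) / step))
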