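"""Dielectric-permittivity → volumetric stem water content calibration.

Frequency-domain reflectometry (FDR) sensors report the dielectric
permittivity ``ε`` of the stem tissue, which rises with water content.  The
general woody-tissue calibration converts the square root of permittivity
linearly to volumetric water content ``θ`` (m³ m⁻³)::

    θ_stem = slope · √ε + intercept            (default 0.2227·√ε − 0.396)

Permittivity also falls with temperature (thermal motion reduces molecular
polarisation), so ``θ_stem`` is corrected to a reference temperature with an
empirical linear term::

    θ_T = θ_stem + (T_stem − T_ref) · β        (default β = −0.000974 °C⁻¹)

Both steps are exactly invertible, which the synthetic-data generator relies
on to turn a prescribed water-content trajectory back into raw sensor
readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "DEFAULT_MODEL",
    "SensorSeries",
    "CalibratedSeries",
    "calibrate_theta",
    "temperature_correct",
    "invert_calibration",
    "calibrate_series",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Coefficients of the two-step FDR calibration.

    Parameters
    ----------
    slope : float
        Gain of the √ε → θ line, m³ m⁻³ per √ε.  Must be positive.
    intercept : float
        Offset of the calibration line, m³ m⁻³.
    beta : float
        Temperature-effect slope, m³ m⁻³ per °C.
    t_ref : float
        Reference stem temperature, °C.
    """

    slope: float = 0.2227
    intercept: float = -0.396
    beta: float = -0.000974
    t_ref: float = 25.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")

    @property
    def epsilon_zero(self) -> float:
        """Permittivity at which the calibration line crosses θ = 0."""
        return (self.intercept / self.slope) ** 2


DEFAULT_MODEL = CalibrationModel()


@dataclass
class SensorSeries:
    """Raw per-tree FDR series on a fixed cadence.

    ``data`` is indexed by timestamp with columns ``epsilon`` (dimensionless
    dielectric permittivity) and ``t_stem`` (°C).  Gaps are represented as
    NaN rows on the regular grid, never as irregular steps.
    """

    tree_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"epsilon", "t_stem"} - set(self.data.columns)
        if missing:
            raise ValueError(f"SensorSeries missing columns: {sorted(missing)}")
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("SensorSeries requires a DatetimeIndex")
        if len(idx) >= 2:
            steps = np.diff(idx.asi8)
            if (steps <= 0).any():
                raise ValueError(
                    f"timestamps of tree {self.tree_id!r} not strictly increasing"
                )
            if len(set(steps)) != 1:
                raise ValueError(
                    f"irregular cadence in tree {self.tree_id!r}; represent gaps "
                    "as missing values on the regular grid"
                )
        eps = self.data["epsilon"].to_numpy(float)
        if np.any(eps[np.isfinite(eps)] <= 0):
            raise ValueError(f"non-positive permittivity in tree {self.tree_id!r}")

    @property
    def cadence(self) -> pd.Timedelta:
        return pd.Timedelta(self.data.index[1] - self.data.index[0])


@dataclass
class CalibratedSeries:
    """Temperature-corrected volumetric water content per tree.

    ``theta`` is a float Series (m³ m⁻³) on the sensor's timestamp grid.
    ``out_of_range`` flags values outside [0, 1]; by default they are kept,
    not clipped, so calibration misuse stays visible.
    """

    tree_id: str
    theta: pd.Series
    out_of_range: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.out_of_range is None:
            self.out_of_range = (self.theta < 0) | (self.theta > 1)


def calibrate_theta(epsilon, model: CalibrationModel = DEFAULT_MODEL):
    """Convert dielectric permittivity to volumetric water content (m³ m⁻³).

    Applies ``slope·√ε + intercept`` elementwise.  NaN propagates; any finite
    non-positive permittivity raises, since √ε is then undefined physically.
    """
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps[np.isfinite(eps)] <= 0):
        raise ValueError("permittivity must be positive")
    out = model.slope * np.sqrt(eps) + model.intercept
    return out if out.ndim else float(out)


def temperature_correct(theta_stem, t_stem, model: CalibrationModel = DEFAULT_MODEL):
    """Correct θ_stem to the reference temperature: θ_T = θ + (T − T_ref)·β."""
    theta = np.asarray(theta_stem, dtype=float)
    t = np.asarray(t_stem, dtype=float)
    out = theta + (t - model.t_ref) * model.beta
    return out if out.ndim else float(out)


def invert_calibration(theta_t, t_stem, model: CalibrationModel = DEFAULT_MODEL):
    """Permittivity that would produce ``theta_t`` at stem temperature ``t_stem``.

    Exact inverse of :func:`calibrate_theta` followed by
    :func:`temperature_correct`; used by the synthetic generator.  Raises if
    the implied uncorrected θ falls at or below the calibration intercept
    (where √ε would be ≤ 0).
    """
    theta = np.asarray(theta_t, dtype=float)
    t = np.asarray(t_stem, dtype=float)
    theta_stem = theta - (t - model.t_ref) * model.beta
    root = (theta_stem - model.intercept) / model.slope
    bad = np.isfinite(root) & (root <= 0)
    if np.any(bad):
        raise ValueError(
            "water content at or below the calibration intercept; "
            "permittivity undefined"
        )
    out = root**2
    return out if out.ndim else float(out)


def calibrate_series(
    raw: SensorSeries,
    model: CalibrationModel = DEFAULT_MODEL,
    clip: bool = False,
) -> CalibratedSeries:
    """Apply the full calibration chain pointwise to a sensor series.

    Missing readings stay missing — gap policy belongs to the daily
    aggregation stage.  With ``clip=True`` the result is clipped to [0, 1]
    (flags still report the original out-of-range points).
    """
    eps = raw.data["epsilon"]
    if eps.dropna().empty:
        raise ValueError(f"tree {raw.tree_id!r}: all permittivity values missing")
    theta_stem = calibrate_theta(eps.to_numpy(), model)
    theta_t = temperature_correct(theta_stem, raw.data["t_stem"].to_numpy(), model)
    theta = pd.Series(theta_t, index=raw.data.index, name="theta")
    flags = (theta < 0) | (theta > 1)
    if clip:
        theta = theta.clip(0.0, 1.0)
    return CalibratedSeries(tree_id=raw.tree_id, theta=theta, out_of_range=flags)
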