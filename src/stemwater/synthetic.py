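"""Synthetic dry-down scenarios with known ground truth.

The generator emulates a seasonal tropical dry-down as seen by stem FDR
sensors, soil TDR probes and a weather station: a wet start, a long drought
with occasional rain pulses, and a late-season rewetting.  Every tree's
water-content trajectory is constructed from known parameters — its turgid
and dry water content, diurnal discharge amplitude, the critical RWC at
which discharge shuts down, and the soil VWC below which overnight refill
fails — so the full analysis pipeline can be tested for parameter recovery
without field data.

Construction, per tree and day:

1. Soil VWC decays exponentially toward a residual floor, recharges with
   rain (Poisson events in the wet phases), plus measurement noise.
2. The nightly-maximum stem θ targets the turgid value while the day's
   maximum soil VWC stays above the tree's refill cutoff; below it, the
   target drops toward the dry value along a sharp exponential knee, and
   the stem state relaxes toward the target with a ~1-day time constant
   (rain pulses therefore rehydrate the stem over a day or two).
3. A sinusoidal diurnal discharge cycle (trough early afternoon, peak
   pre-dawn) is subtracted.  Its amplitude is the tree's diurnal amplitude
   scaled by a sigmoid of daily-max RWC that collapses to a few percent
   below the tree's critical RWC — the discharge shut-down the strain
   analysis should rediscover.
4. θ is converted to dielectric permittivity through the exact inverse of
   the calibration chain at the simulated stem temperature, and Gaussian
   sensor noise is added.

Identical seed and configuration give bit-identical output; each tree uses
an independent RNG stream spawned deterministically from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, DEFAULT_MODEL, SensorSeries, invert_calibration
from .hydration import TreeSpec
from .soil import SoilSeries

__all__ = [
    "SeasonParams",
    "SoilParams",
    "ClimateParams",
    "NoiseParams",
    "TreeTruth",
    "ScenarioConfig",
    "Scenario",
    "default_trees",
    "default_truths",
    "generate_scenario",
    "write_scenario",
]


@dataclass(frozen=True)
class SeasonParams:
    """Wet → dry → rewet phase boundaries, in days from the series start."""

    wet_end_day: int = 20
    rewet_start_day: int = 140


@dataclass(frozen=True)
class SoilParams:
    """Soil water balance at the reference depth (m³ m⁻³, day⁻¹, per mm)."""

    initial_vwc: float = 0.29
    floor_vwc: float = 0.10
    decay_rate: float = 0.02
    recharge_per_mm: float = 0.0005
    depths_cm: tuple[int, ...] = (100, 250, 400)
    reference_max: float = 0.2923  # long-term 99th-percentile VWC


@dataclass(frozen=True)
class ClimateParams:
    """Diurnal temperature/humidity cycles and rainfall statistics."""

    t_mean: float = 28.0
    t_amplitude: float = 4.0
    rh_min: float = 60.0
    rh_max: float = 95.0
    rain_rate_wet: float = 1.0  # events day⁻¹ during wet phases
    rain_rate_dry: float = 0.03
    rain_depth_mm: float = 8.0  # mean event depth


@dataclass(frozen=True)
class NoiseParams:
    """Measurement noise standard deviations."""

    epsilon_sd: float = 0.01
    soil_sd: float = 0.002


@dataclass(frozen=True)
class TreeTruth:
    """Ground-truth parameters embedded in one tree's trajectory."""

    tree_id: str
    theta_turgid_true: float
    theta_dry_true: float
    diurnal_amp_true: float
    rwc_crit_true: float
    refill_cutoff_soil_vwc_true: float

    def __post_init__(self) -> None:
        if not 0 < self.theta_dry_true < self.theta_turgid_true < 1:
            raise ValueError(
                f"{self.tree_id}: need 0 < θ_dry < θ_turgid < 1, got "
                f"{self.theta_dry_true} / {self.theta_turgid_true}"
            )
        if not self.rwc_crit_true < 1:
            raise ValueError(f"{self.tree_id}: rwc_crit_true must be < 1")


def default_trees() -> list[TreeSpec]:
    """The default stand: two palms and five subcanopy dicots."""
    return [
        TreeSpec("palm_01", "palm", height=20.0, dbh=0.22, wood_density=0.63),
        TreeSpec("palm_02", "palm", height=13.0, dbh=0.22, wood_density=0.29),
        TreeSpec("dicot_01", "dicot", height=18.0, dbh=0.20, wood_density=0.54,
                 sapwood_depth=0.032),
        TreeSpec("dicot_02", "dicot", height=22.0, dbh=0.25, wood_density=0.82,
                 sapwood_depth=0.040),
        TreeSpec("dicot_03", "dicot", height=20.0, dbh=0.22, wood_density=0.69,
                 sapwood_depth=0.035),
        TreeSpec("dicot_04", "dicot", height=16.0, dbh=0.18, wood_density=0.75,
                 sapwood_depth=0.029),
        TreeSpec("dicot_05", "dicot", height=17.0, dbh=0.19, wood_density=0.75,
                 sapwood_depth=0.030),
    ]


# Group-level truth templates: palms store more water, discharge more, and
# tolerate lower relative hydration before discharge shuts down.
_PALM_TRUTH = dict(theta_turgid=0.70, diurnal_amp=0.048, rwc_crit=0.68)
_DICOT_TRUTH = dict(theta_turgid=0.41, diurnal_amp=0.018, rwc_crit=0.81)
# Dry-value offset: the drought bottoms out slightly below the critical RWC.
_RWC_FLOOR_BELOW_CRIT = 0.04


def default_truths(
    trees: list[TreeSpec],
    refill_cutoff: float = 0.19,
    jitter_rng: np.random.Generator | None = None,
) -> list[TreeTruth]:
    """Per-tree ground truth from the group templates, with mild jitter."""
    out = []
    for tree in trees:
        tpl = _PALM_TRUTH if tree.group == "palm" else _DICOT_TRUTH
        j = (
            jitter_rng.normal(0, [0.02, 0.1, 0.01])
            if jitter_rng is not None
            else np.zeros(3)
        )
        turgid = float(np.clip(tpl["theta_turgid"] + j[0], 0.05, 0.95))
        rwc_crit = float(np.clip(tpl["rwc_crit"] + j[2], 0.3, 0.97))
        out.append(
            TreeTruth(
                tree_id=tree.tree_id,
                theta_turgid_true=turgid,
                theta_dry_true=turgid * (rwc_crit - _RWC_FLOOR_BELOW_CRIT),
                diurnal_amp_true=float(tpl["diurnal_amp"] * (1 + 0.1 * j[1])),
                rwc_crit_true=rwc_crit,
                refill_cutoff_soil_vwc_true=refill_cutoff,
            )
        )
    return out


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one deterministic scenario."""

    n_days: int = 163
    cadence_minutes: int = 15
    trees: tuple[TreeSpec, ...] = field(default_factory=lambda: tuple(default_trees()))
    truths: tuple[TreeTruth, ...] | None = None  # derived from trees when None
    season: SeasonParams = SeasonParams()
    soil: SoilParams = SoilParams()
    climate: ClimateParams = ClimateParams()
    noise: NoiseParams = NoiseParams()
    start: str = "2023-07-01"
    knee_width: float = 0.015  # m³ m⁻³, sharpness of the refill-failure knee
    stem_relax_days: float = 1.0
    amp_sigmoid_width: float = 0.01  # RWC units, discharge shut-down width
    amp_floor_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError(f"n_days must be ≥ 2, got {self.n_days}")
        if 1440 % self.cadence_minutes:
            raise ValueError(
                f"cadence_minutes must divide 1440, got {self.cadence_minutes}"
            )
        for name in ("epsilon_sd", "soil_sd"):
            if getattr(self.noise, name) < 0:
                raise ValueError(f"noise.{name} must be ≥ 0")
        if not 0 < self.soil.initial_vwc < 1:
            raise ValueError(
                f"soil.initial_vwc must lie in (0, 1), got {self.soil.initial_vwc}"
            )


@dataclass
class Scenario:
    """Generated series plus the ground truth that produced them."""

    sensors: list[SensorSeries]
    soil: SoilSeries
    meteo: pd.DataFrame
    truths: list[TreeTruth]
    config: ScenarioConfig


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_scenario(
    config: ScenarioConfig,
    calibration: CalibrationModel = DEFAULT_MODEL,
) -> Scenario:
    """Generate sensor, soil and meteorological series for one scenario."""
    rng = np.random.default_rng(config.seed)
    tree_rngs = rng.spawn(len(config.trees))

    steps_per_day = 1440 // config.cadence_minutes
    n = config.n_days * steps_per_day
    index = pd.date_range(
        config.start, periods=n, freq=f"{config.cadence_minutes}min"
    )
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    day_of = np.repeat(np.arange(config.n_days), steps_per_day)

    # --- climate -----------------------------------------------------------
    cl = config.climate
    t_air = cl.t_mean + cl.t_amplitude * np.sin(2 * np.pi * (hour - 9.0) / 24.0)
    rh = cl.rh_max - (cl.rh_max - cl.rh_min) * (
        (t_air - (cl.t_mean - cl.t_amplitude)) / (2 * cl.t_amplitude)
    )
    rain = np.zeros(n)
    wet_phase = (np.arange(config.n_days) < config.season.wet_end_day) | (
        np.arange(config.n_days) >= config.season.rewet_start_day
    )
    for d in range(config.n_days):
        rate = cl.rain_rate_wet if wet_phase[d] else cl.rain_rate_dry
        for _ in range(rng.poisson(rate)):
            slot = d * steps_per_day + rng.integers(steps_per_day)
            rain[slot] += rng.exponential(cl.rain_depth_mm)
    meteo = pd.DataFrame(
        {"t_air": t_air, "rh": rh, "precipitation": rain}, index=index
    )
    meteo.index.name = "timestamp"

    # --- soil --------------------------------------------------------------
    sp = config.soil
    dt_days = config.cadence_minutes / 1440.0
    vwc = np.empty(n)
    v = sp.initial_vwc
    for i in range(n):
        v = v - sp.decay_rate * dt_days * (v - sp.floor_vwc) + sp.recharge_per_mm * rain[i]
        v = min(v, 0.99)
        vwc[i] = v
    vwc_noisy = np.clip(vwc + rng.normal(0, config.noise.soil_sd, n), 1e-3, 0.999)
    # deeper horizons: damped copies (not used by the headline analysis)
    soil_cols = {f"{sp.depths_cm[0]}cm": vwc_noisy}
    for depth in sp.depths_cm[1:]:
        damp = 0.6 * sp.depths_cm[0] / depth + 0.4
        damped = sp.floor_vwc + (vwc - sp.floor_vwc) * damp
        soil_cols[f"{depth}cm"] = np.clip(
            damped + rng.normal(0, config.noise.soil_sd, n), 1e-3, 0.999
        )
    hourly = pd.DataFrame(soil_cols, index=index).resample("1h").mean()
    hourly.index.name = "timestamp"
    soil = SoilSeries(data=hourly, reference_max=sp.reference_max)

    # daily max of the *clean* reference-depth soil drives the stem response
    soil_day_max = (
        pd.Series(vwc, index=index).groupby(day_of).max().to_numpy()
    )

    # --- stem temperature (shared diurnal sinusoid) ------------------------
    t_stem = cl.t_mean + cl.t_amplitude * np.sin(2 * np.pi * (hour - 10.0) / 24.0)

    # --- trees -------------------------------------------------------------
    truths = (
        list(config.truths)
        if config.truths is not None
        else default_truths(list(config.trees))
    )
    if len(truths) != len(config.trees):
        raise ValueError("truths must match trees one-to-one")
    # diurnal shape in [0, 1]: 0 pre-dawn (~01:00), 1 early afternoon (13:00)
    shape = 0.5 * (1.0 + np.sin(2 * np.pi * (hour - 7.0) / 24.0))

    sensors = []
    for tree, truth, trng in zip(config.trees, truths, tree_rngs):
        turgid, dry = truth.theta_turgid_true, truth.theta_dry_true
        deficit = np.maximum(0.0, truth.refill_cutoff_soil_vwc_true - soil_day_max)
        target = turgid - (turgid - dry) * (1.0 - np.exp(-deficit / config.knee_width))
        base = np.empty(config.n_days)
        b = turgid
        relax = 1.0 - np.exp(-1.0 / config.stem_relax_days)
        for d in range(config.n_days):
            b = b + (target[d] - b) * relax
            base[d] = b
        rwc_day = base / turgid
        amp = truth.diurnal_amp_true * (
            config.amp_floor_frac
            + (1 - config.amp_floor_frac)
            * _sigmoid((rwc_day - truth.rwc_crit_true) / config.amp_sigmoid_width)
        )
        theta = base[day_of] - amp[day_of] * shape
        eps = invert_calibration(theta, t_stem, calibration)
        eps_noisy = eps + trng.normal(0, config.noise.epsilon_sd, n)
        eps_noisy = np.maximum(eps_noisy, calibration.epsilon_zero * 1.0001 + 1e-9)
        data = pd.DataFrame({"epsilon": eps_noisy, "t_stem": t_stem}, index=index)
        data.index.name = "timestamp"
        sensors.append(SensorSeries(tree_id=tree.tree_id, data=data))

    return Scenario(
        sensors=sensors, soil=soil, meteo=meteo, truths=truths, config=config
    )


def write_scenario(scenario: Scenario, directory) -> dict[str, str]:
    """Write a scenario to the package's CSV dialects; returns the paths."""
    from . import io as _io

    return _io.write_scenario_csvs(scenario, directory)
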