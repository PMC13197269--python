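"""CSV formats, run configuration and end-to-end pipeline orchestration.

All files are comma-separated UTF-8 with a mandatory header, ``.`` decimal
separator, ISO 8601 timestamps in local site time, and empty fields for
missing values.  Formats:

* sensor CSV   — ``timestamp,tree_id,epsilon,t_stem`` (long form, all trees)
* soil CSV     — ``timestamp,<depth>,...`` one column per depth label
* meteo CSV    — ``timestamp,t_air,rh,precipitation``
* tree CSV     — ``tree_id,group,height,dbh,wood_density,sapwood_depth``
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationModel, SensorSeries, calibrate_series
from .hydration import (
    TreeSpec,
    active_storage,
    storage_metrics,
    summarise_days,
)
from .inference import group_contrast
from .meteorology import daily_max_vpd
from .soil import SoilSeries, daily_pairs, soil_threshold_analysis
from .strain import capacity_series, strain_thresholds, vpd_capacity_correlation
from .util import DAY_COMPLETENESS, percentile

__all__ = [
    "RunConfig",
    "read_sensor_csv",
    "read_soil_csv",
    "read_meteo_csv",
    "read_trees_csv",
    "write_scenario_csvs",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Paths, analysis settings and output location for one pipeline run."""

    sensor_csv: str
    soil_csv: str
    meteo_csv: str
    trees_csv: str
    output_dir: str
    calibration: CalibrationModel = field(default_factory=CalibrationModel)
    soil_reference_max: float = 0.2923
    soil_depth: str = "100cm"
    percentile_hi: float = 99.0
    percentile_lo: float = 1.0
    day_completeness: float = DAY_COMPLETENESS
    rwc_exclusion: float = 0.95
    gam_k: int = 6
    gam_grid: int = 200
    gam_draws: int = 1000
    n_permutations: int = 5000
    seed: int = 0
    clip_theta: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cal = raw.pop("calibration", None)
        cfg = cls(**raw)
        if cal:
            cfg.calibration = CalibrationModel(**cal)
        if not 0 < cfg.rwc_exclusion < 1:
            raise ValueError(f"rwc_exclusion must lie in (0,1), got {cfg.rwc_exclusion}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _read_timestamped(path, parse_cols) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"timestamp", *parse_cols} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_sensor_csv(path) -> list[SensorSeries]:
    """Read a long-form sensor CSV into one validated series per tree."""
    df = _read_timestamped(path, ["tree_id", "epsilon", "t_stem"])
    out = []
    for tree_id, sub in df.groupby("tree_id", sort=True):
        sub = sub.set_index("timestamp")[["epsilon", "t_stem"]]
        out.append(SensorSeries(tree_id=str(tree_id), data=sub))
    return out


def read_soil_csv(path, reference_max: float) -> SoilSeries:
    df = _read_timestamped(path, [])
    if df.shape[1] < 2:
        raise ValueError(f"{path}: soil CSV needs at least one depth column")
    return SoilSeries(
        data=df.set_index("timestamp"), reference_max=reference_max
    )


def read_meteo_csv(path) -> pd.DataFrame:
    df = _read_timestamped(path, ["t_air", "rh", "precipitation"])
    return df.set_index("timestamp")


def read_trees_csv(path) -> list[TreeSpec]:
    df = pd.read_csv(path)
    required = {"tree_id", "group"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    trees = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in ("height", "dbh", "wood_density", "sapwood_depth"):
            if col in df.columns and pd.notna(row.get(col)):
                kwargs[col] = float(row[col])
        trees.append(TreeSpec(str(row["tree_id"]), str(row["group"]), **kwargs))
    return trees


def write_scenario_csvs(scenario, directory) -> dict[str, str]:
    """Write a generated scenario in the package's CSV dialects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = []
    for s in scenario.sensors:
        frame = s.data.reset_index()
        frame.insert(1, "tree_id", s.tree_id)
        frames.append(frame)
    sensor = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["timestamp", "tree_id", "epsilon", "t_stem"])
    )
    paths = {
        "sensor": directory / "sensor.csv",
        "soil": directory / "soil.csv",
        "meteo": directory / "meteo.csv",
        "trees": directory / "trees.csv",
    }
    sensor.to_csv(paths["sensor"], index=False, float_format="%.6f")
    scenario.soil.data.reset_index().to_csv(
        paths["soil"], index=False, float_format="%.6f"
    )
    scenario.meteo.reset_index().to_csv(
        paths["meteo"], index=False, float_format="%.6f"
    )
    pd.DataFrame([dataclasses.asdict(t) for t in scenario.config.trees]).to_csv(
        paths["trees"], index=False
    )
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute calibrate → daily summaries → storage → strain → soil
    threshold → group contrasts, writing all outputs under ``output_dir``.

    Returns a result bundle with the output paths and the in-memory tables.
    Deterministic given ``config.seed``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sensors = _stage("read sensors", read_sensor_csv, config.sensor_csv)
    soil = _stage(
        "read soil", read_soil_csv, config.soil_csv, config.soil_reference_max
    )
    meteo = _stage("read meteo", read_meteo_csv, config.meteo_csv)
    trees = {t.tree_id: t for t in _stage("read trees", read_trees_csv, config.trees_csv)}

    storage_rows, strain_rows, day_tables = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vpd_daily = daily_max_vpd(meteo, p=config.percentile_hi,
                                  completeness=config.day_completeness)
    for sensor in sensors:
        cal = calibrate_series(sensor, config.calibration, clip=config.clip_theta)
        theta_t = percentile(cal.theta.dropna().to_numpy(), config.percentile_hi)
        days = summarise_days(
            cal,
            theta_turgid=float(theta_t),
            completeness=config.day_completeness,
            p_hi=config.percentile_hi,
            p_lo=config.percentile_lo,
        )
        metrics = storage_metrics(cal, days, config.percentile_hi, config.percentile_lo)
        tree = trees.get(sensor.tree_id)
        row = dataclasses.asdict(metrics)
        if tree is not None and tree.height and tree.dbh:
            row["active_storage"] = active_storage(tree, metrics.theta_turgid)
            row["group"] = tree.group
        storage_rows.append(row)

        strain_days = capacity_series(days, metrics.diurnal_delta, config.rwc_exclusion)
        result = strain_thresholds(strain_days, tree_id=sensor.tree_id)
        try:
            r = vpd_capacity_correlation(strain_days, vpd_daily, config.rwc_exclusion)
        except ValueError:
            r = float("nan")
        srow = dataclasses.asdict(result)
        srow["vpd_capacity_r"] = r
        srow["rwc_crit_label"] = result.rwc_crit_label
        strain_rows.append(srow)
        day_tables.append(strain_days)

    storage_df = pd.DataFrame(storage_rows)
    strain_df = pd.DataFrame(strain_rows)
    all_days = pd.concat(day_tables)

    groups = {tid: t.group for tid, t in trees.items()}
    pairs = _stage(
        "soil pairing", daily_pairs, all_days, soil, config.soil_depth, groups
    )
    fit, grid, threshold = _stage(
        "soil threshold",
        soil_threshold_analysis,
        pairs,
        config.gam_k,
        config.gam_grid,
        config.gam_draws,
        config.seed,
    )

    contrasts = []
    if storage_df.get("group") is not None and storage_df["group"].notna().all():
        for metric in ("theta_turgid", "seasonal_delta", "diurnal_delta"):
            contrasts.append(
                dataclasses.asdict(
                    group_contrast(
                        metric,
                        storage_df[metric].to_numpy(),
                        storage_df["group"].to_numpy(),
                        n_perm=config.n_permutations,
                        seed=config.seed,
                    )
                )
            )
    contrast_df = pd.DataFrame(contrasts)

    paths = {
        "storage": out_dir / "storage_metrics.csv",
        "strain": out_dir / "strain_results.csv",
        "strain_days": out_dir / "strain_days.csv",
        "derivative_grid": out_dir / "derivative_grid.csv",
        "threshold": out_dir / "threshold.json",
        "contrasts": out_dir / "contrasts.csv",
        "run_log": out_dir / "run_log.json",
    }
    storage_df.to_csv(paths["storage"], index=False)
    strain_df.to_csv(paths["strain"], index=False)
    all_days.reset_index().to_csv(paths["strain_days"], index=False)
    grid.to_csv(paths["derivative_grid"], index=False)
    with open(paths["threshold"], "w") as fh:
        json.dump(
            {
                "threshold_vwc": threshold.threshold_vwc,
                "threshold_soil_rwc": (
                    None
                    if threshold.threshold_vwc is None
                    else threshold.threshold_vwc / soil.reference_max
                ),
                "qualifying_run": threshold.qualifying_run,
                "r_squared": fit.r_squared,
                "edf": fit.edf,
                "n_pairs": fit.n_obs,
            },
            fh,
            indent=2,
        )
    contrast_df.to_csv(paths["contrasts"], index=False)
    with open(paths["run_log"], "w") as fh:
        json.dump(
            {
                "stemwater_version": __version__,
                "numpy_version": np.__version__,
                "pandas_version": pd.__version__,
                "seed": config.seed,
                "config": _jsonable(config.to_dict()),
            },
            fh,
            indent=2,
        )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "storage": storage_df,
        "strain": strain_df,
        "threshold": threshold,
        "fit": fit,
        "grid": grid,
        "contrasts": contrast_df,
    }


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
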