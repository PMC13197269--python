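"""Hydraulic-strain classification and critical hydration thresholds.

A day's *relative diurnal discharge capacity* is its θ range as a percentage
of the tree's maximum diurnal discharge (the 99th percentile of daily
ranges).  Reduced capacity under drought is read as hydraulic strain —
the internally expressed functional deviation under the external stress —
and binned as:

* severe   capacity < 5 %
* high     5 % ≤ capacity < 10 %
* moderate 10 % ≤ capacity < 20 %
* none     otherwise

Days with daily-max RWC > 0.95 are excluded from strain statistics: at high
hydration a small range reflects water abundance, not impairment.  Two
thresholds summarise each tree:

* RWC_crit — mean daily-max RWC over (non-excluded) days with capacity
  < 10 %: hydration at which diurnal water mobilisation is critically
  impaired.  When no such day exists the tree never reached impairment and
  the threshold is reported as a censored upper bound "< min RWC".
* RWC_mrc — mean daily-max RWC over days with capacity > 75 %, computed on
  the full record including high-hydration days: near-optimal functioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STRAIN_BINS",
    "RWC_EXCLUSION",
    "StrainResult",
    "classify_strain",
    "capacity_series",
    "strain_thresholds",
    "vpd_capacity_correlation",
]

# Half-open capacity bins, lower bound inclusive.
STRAIN_BINS = {"severe": (0.0, 5.0), "high": (5.0, 10.0), "moderate": (10.0, 20.0)}
RWC_EXCLUSION = 0.95
CRIT_CAPACITY = 10.0
MRC_CAPACITY = 75.0


@dataclass(frozen=True)
class StrainResult:
    """Per-tree strain thresholds and drought-exposure day counts.

    ``rwc_crit`` is NaN when censored (no day below 10 % capacity); the
    reachable bound is then ``rwc_crit_bound`` and ``rwc_crit_censored`` is
    True.  ``d_crit_10``/``d_crit_5`` count non-excluded days below 10 % and
    5 % capacity; ``d_mod`` counts moderate-strain days.
    """

    tree_id: str
    rwc_crit: float
    rwc_crit_sd: float
    rwc_crit_censored: bool
    rwc_crit_bound: float
    rwc_mrc: float
    rwc_mrc_sd: float
    rwc_min: float
    d_crit_10: int
    d_crit_5: int
    d_mod: int
    vpd_capacity_r: float = float("nan")

    @property
    def rwc_crit_label(self) -> str:
        """Human-readable threshold, e.g. ``"0.68"`` or censored ``"< 0.73"``."""
        if self.rwc_crit_censored:
            return f"< {self.rwc_crit_bound:.2f}"
        return f"{self.rwc_crit:.2f}"


def classify_strain(capacity_pct: float) -> str:
    """Strain class of a single day's relative discharge capacity (%)."""
    if not np.isfinite(capacity_pct) or capacity_pct < 0:
        raise ValueError(f"capacity_pct must be finite and ≥ 0, got {capacity_pct}")
    for name, (lo, hi) in STRAIN_BINS.items():
        if lo <= capacity_pct < hi:
            return name
    return "none"


def capacity_series(
    days: pd.DataFrame,
    diurnal_delta_max: float,
    rwc_exclusion: float = RWC_EXCLUSION,
) -> pd.DataFrame:
    """Attach relative discharge capacity and strain class to daily summaries.

    ``days`` is the output of :func:`stemwater.hydration.summarise_days`.
    ``capacity_pct`` = 100·daily_range/diurnal_delta_max; days with
    ``rwc_day_max`` above the exclusion cutoff are classed ``"excluded"``.
    """
    if not diurnal_delta_max > 0:
        raise ValueError(
            f"diurnal_delta_max must be > 0 (degenerate tree), got {diurnal_delta_max}"
        )
    out = days.copy()
    out["capacity_pct"] = 100.0 * out["daily_range"] / diurnal_delta_max
    out["strain_class"] = [classify_strain(c) for c in out["capacity_pct"]]
    out.loc[out["rwc_day_max"] > rwc_exclusion, "strain_class"] = "excluded"
    return out


def strain_thresholds(days: pd.DataFrame, tree_id: str | None = None) -> StrainResult:
    """Derive RWC_crit, RWC_mrc, RWC_min and exposure day counts for one tree.

    ``days`` is the output of :func:`capacity_series`.  RWC_min is the
    minimum of daily maxima (the driest hydration status reached).
    """
    if days.empty:
        raise ValueError("no days to analyse")
    if tree_id is None:
        tree_id = str(days["tree_id"].iloc[0]) if "tree_id" in days else ""
    kept = days[days["strain_class"] != "excluded"]
    crit_days = kept[kept["capacity_pct"] < CRIT_CAPACITY]
    rwc_min = float(days["rwc_day_max"].min())
    if len(crit_days):
        rwc_crit = float(crit_days["rwc_day_max"].mean())
        rwc_crit_sd = (
            float(crit_days["rwc_day_max"].std(ddof=1))
            if len(crit_days) > 1
            else float("nan")
        )
        censored = False
    else:
        rwc_crit, rwc_crit_sd, censored = float("nan"), float("nan"), True
    mrc_days = days[days["capacity_pct"] > MRC_CAPACITY]
    if len(mrc_days):
        rwc_mrc = float(mrc_days["rwc_day_max"].mean())
        rwc_mrc_sd = (
            float(mrc_days["rwc_day_max"].std(ddof=1))
            if len(mrc_days) > 1
            else float("nan")
        )
    else:
        rwc_mrc, rwc_mrc_sd = float("nan"), float("nan")
    return StrainResult(
        tree_id=tree_id,
        rwc_crit=rwc_crit,
        rwc_crit_sd=rwc_crit_sd,
        rwc_crit_censored=censored,
        rwc_crit_bound=rwc_min,
        rwc_mrc=rwc_mrc,
        rwc_mrc_sd=rwc_mrc_sd,
        rwc_min=rwc_min,
        d_crit_10=int((kept["capacity_pct"] < CRIT_CAPACITY).sum()),
        d_crit_5=int((kept["capacity_pct"] < STRAIN_BINS["severe"][1]).sum()),
        d_mod=int((kept["strain_class"] == "moderate").sum()),
    )


def vpd_capacity_correlation(
    days: pd.DataFrame,
    daily_vpd: pd.Series,
    rwc_exclusion: float = RWC_EXCLUSION,
) -> float:
    """Pearson r between daily max VPD and discharge capacity on stress days.

    Stress days are those with daily-max RWC ≤ the exclusion cutoff.  A weak
    or negative r indicates plant regulation (stomatal closure) rather than
    atmospheric demand driving the capacity decline.  Raises when fewer than
    three paired stress days exist or either side is constant.
    """
    stress = days[days["rwc_day_max"] <= rwc_exclusion]
    joined = stress.join(daily_vpd.rename("vpd_max"), how="inner").dropna(
        subset=["capacity_pct", "vpd_max"]
    )
    if len(joined) < 3:
        raise ValueError(f"need ≥3 paired stress days, have {len(joined)}")
    x = joined["vpd_max"].to_numpy()
    y = joined["capacity_pct"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in VPD or capacity; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
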