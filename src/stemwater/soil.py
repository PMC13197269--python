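"""Soil-moisture → stem-hydration response curves and breakpoint detection.

Daily maximum stem RWC is regressed on daily maximum soil volumetric water
content with a penalized cubic B-spline smooth (basis dimension ``k``,
default 6; curvature penalty; smoothing parameter chosen by REML).  The
fitted smooth's first derivative, with a simulation-based 95% confidence
band, locates the soil-moisture threshold at which stem water reserves
enter a sustained rapid-decline zone.

Sign convention: the decline of interest happens as soil *dries*, so the
threshold scan operates on the drying-direction derivative, −dRWC/dVWC,
which is strongly negative inside the decline zone.  A grid point qualifies
when its upper confidence limit is below zero *and* its derivative lies in
the strongest-negative quartile of the grid; the threshold is the first
grid point (scanning from wet to dry) that opens a run of at least five
consecutive qualifying points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar

__all__ = [
    "SoilSeries",
    "SmoothFit",
    "ThresholdResult",
    "daily_pairs",
    "fit_smooth",
    "derivative_with_ci",
    "detect_threshold",
    "compare_groups",
    "soil_threshold_analysis",
]

MIN_RUN = 5


@dataclass
class SoilSeries:
    """Timestamped soil VWC by depth plus a long-term normalisation maximum.

    ``data`` is timestamp-indexed with one column per depth label (e.g.
    ``"100cm"``); ``reference_max`` is the long-term 99th-percentile VWC used
    for soil relative water content.
    """

    data: pd.DataFrame
    reference_max: float

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("SoilSeries requires a DatetimeIndex")
        if not self.reference_max > 0:
            raise ValueError(f"reference_max must be > 0, got {self.reference_max}")

    def daily_max(self, depth: str) -> pd.Series:
        if depth not in self.data.columns:
            raise KeyError(
                f"depth {depth!r} not in soil data (have {list(self.data.columns)})"
            )
        col = self.data[depth]
        out = col.groupby(col.index.date).max().dropna()
        out.index.name = "date"
        return out.rename("soil_vwc")


@dataclass
class SmoothFit:
    """A fitted penalized-spline smooth of stem RWC on soil VWC."""

    group: str
    k: int
    knots: np.ndarray = field(repr=False)
    coef: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)  # Bayesian posterior covariance
    lambda_: float
    sigma2: float
    edf: float
    rss: float
    n_obs: int
    r_squared: float
    x_min: float
    x_max: float

    def predict(self, x) -> np.ndarray:
        """Population smooth evaluated at soil VWC values ``x``."""
        X = _design(np.asarray(x, float), self.knots)
        return X @ self.coef

    def predict_ci(self, x, level: float = 0.95):
        """(fit, lower, upper) with pointwise Gaussian-posterior intervals."""
        X = _design(np.asarray(x, float), self.knots)
        fit = X @ self.coef
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov, X))
        z = stats.norm.ppf(0.5 + level / 2)
        return fit, fit - z * se, fit + z * se


@dataclass
class ThresholdResult:
    """Outcome of the sustained rapid-decline scan.

    ``threshold_vwc`` is None when no qualifying run of length ≥ ``min_run``
    exists (a valid result: no breakpoint in range).  ``qualifying_run`` holds
    the integer positions (into the ascending-VWC grid) of the detected run,
    wet end first; ``criteria_trace`` records the per-point booleans.
    """

    threshold_vwc: float | None
    qualifying_run: tuple[int, int] | None
    criteria_trace: pd.DataFrame = field(repr=False)


# --------------------------------------------------------------------------
# basis and penalty


def _knot_vector(x_min: float, x_max: float, k: int) -> np.ndarray:
    """Open cubic-B-spline knot vector with k basis functions.

    Interior knots (k − 4 of them) are evenly spaced across the data range;
    boundary knots have multiplicity 4.
    """
    if k < 4:
        raise ValueError(f"basis dimension k must be ≥ 4 for cubic splines, got {k}")
    interior = np.linspace(x_min, x_max, k - 2)[1:-1]
    return np.concatenate([[x_min] * 4, interior, [x_max] * 4])


def _design(x: np.ndarray, knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Design matrix (or its ``deriv``-th derivative) of the cubic basis."""
    k = len(knots) - 4
    x = np.clip(x, knots[0], knots[-1])  # evaluate at boundary, not outside
    cols = []
    for i in range(k):
        e = np.zeros(k)
        e[i] = 1.0
        b = BSpline(knots, e, 3, extrapolate=False)
        if deriv:
            b = b.derivative(deriv)
        v = b(x)
        cols.append(np.nan_to_num(v))
    return np.column_stack(cols)


def _curvature_penalty(knots: np.ndarray) -> np.ndarray:
    """S_ij = ∫ B_i'' B_j'' dx via Gauss–Legendre, exact for cubic splines."""
    k = len(knots) - 4
    nodes, weights = np.polynomial.legendre.leggauss(3)
    S = np.zeros((k, k))
    breaks = np.unique(knots)
    for a, b in zip(breaks[:-1], breaks[1:]):
        xm, xr = (a + b) / 2, (b - a) / 2
        xs = xm + xr * nodes
        D2 = _design(xs, knots, deriv=2)
        S += xr * (D2.T * weights) @ D2
    return S


# --------------------------------------------------------------------------
# fitting


def daily_pairs(
    stem_days: pd.DataFrame,
    soil: SoilSeries,
    depth: str,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join per-tree daily stem summaries with daily maximum soil VWC.

    ``stem_days`` is a concatenation of :func:`stemwater.hydration.summarise_days`
    outputs (date-indexed, with ``tree_id`` and ``rwc_day_max``); ``groups``
    maps tree_id → ``"palm"``/``"dicot"``.  Days missing on either side are
    dropped; no overlap at all is an error.
    """
    soil_daily = soil.daily_max(depth)
    df = stem_days.reset_index()[["date", "tree_id", "rwc_day_max"]].rename(
        columns={"rwc_day_max": "stem_rwc"}
    )
    merged = df.merge(soil_daily.reset_index(), on="date", how="inner").dropna(
        subset=["soil_vwc", "stem_rwc"]
    )
    if merged.empty:
        raise ValueError("no overlapping dates between stem and soil series")
    if groups is not None:
        merged["group"] = merged["tree_id"].map(groups)
    return merged


def fit_smooth(
    pairs: pd.DataFrame,
    group: str = "pooled",
    k: int = 6,
) -> SmoothFit:
    """Penalized cubic regression spline of stem RWC on soil VWC.

    ``pairs`` must contain ``soil_vwc`` and ``stem_rwc`` columns (rows for
    ``group`` only are used unless ``group`` is ``"pooled"``).  The smoothing
    parameter minimises the (profiled) restricted marginal likelihood; if
    that optimisation fails, generalized cross-validation is used with a
    warning.  Confidence statements come from the Gaussian approximation to
    the coefficient posterior, ``β ~ N(β̂, σ²(XᵀX + λS)⁻¹)``.
    """
    sub = pairs if group == "pooled" else pairs[pairs["group"] == group]
    x = sub["soil_vwc"].to_numpy(float)
    y = sub["stem_rwc"].to_numpy(float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < k:
        raise ValueError(
            f"need ≥{k} distinct soil VWC values, have {len(np.unique(x))}"
        )
    knots = _knot_vector(x.min(), x.max(), k)
    X = _design(x, knots)
    S = _curvature_penalty(knots)
    XtX, Xty = X.T @ X, X.T @ y
    n = len(y)
    null_dim = 2  # straight lines are unpenalized
    pos_eig = np.linalg.eigvalsh(S)
    pos_eig = pos_eig[pos_eig > 1e-10 * pos_eig.max()]
    ldet_S_plus = float(np.sum(np.log(pos_eig)))
    rank_S = len(pos_eig)

    def beta_for(lam: float) -> np.ndarray:
        return np.linalg.solve(XtX + lam * S, Xty)

    def reml_score(rho: float) -> float:
        lam = np.exp(rho)
        A = XtX + lam * S
        beta = np.linalg.solve(A, Xty)
        rss = float(np.sum((y - X @ beta) ** 2))
        pen = float(lam * beta @ S @ beta)
        _, ldet_A = np.linalg.slogdet(A)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = 0.5 * (n - null_dim) * np.log(rss + pen) + 0.5 * (
                ldet_A - (rank_S * rho + ldet_S_plus)
            )
        return score if np.isfinite(score) else 1e10

    def gcv_score(rho: float) -> float:
        lam = np.exp(rho)
        A = XtX + lam * S
        beta = np.linalg.solve(A, Xty)
        rss = float(np.sum((y - X @ beta) ** 2))
        tr = float(np.trace(np.linalg.solve(A, XtX)))
        score = n * rss / (n - tr) ** 2
        return score if np.isfinite(score) else 1e10

    try:
        res = minimize_scalar(reml_score, bounds=(-20.0, 25.0), method="bounded")
        if not res.success or not np.isfinite(res.fun):
            raise RuntimeError(res.message)
        rho = float(res.x)
    except Exception as exc:  # pragma: no cover - REML rarely fails
        warnings.warn(f"REML selection failed ({exc}); falling back to GCV")
        rho = float(
            minimize_scalar(gcv_score, bounds=(-20.0, 25.0), method="bounded").x
        )

    lam = float(np.exp(rho))
    A = XtX + lam * S
    beta = beta_for(lam)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    edf = float(np.trace(np.linalg.solve(A, XtX)))
    sigma2 = rss / (n - edf)
    cov = sigma2 * np.linalg.inv(A)
    tss = float(np.sum((y - y.mean()) ** 2))
    return SmoothFit(
        group=group,
        k=k,
        knots=knots,
        coef=beta,
        cov=cov,
        lambda_=lam,
        sigma2=sigma2,
        edf=edf,
        rss=rss,
        n_obs=n,
        r_squared=1.0 - rss / tss if tss > 0 else float("nan"),
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def derivative_with_ci(
    fit: SmoothFit,
    n_grid: int = 200,
    n_draws: int = 1000,
    seed: int | None = None,
    drying: bool = False,
) -> pd.DataFrame:
    """First derivative of the smooth on a uniform grid with 95% bands.

    The derivative is analytic (derivative of the spline basis); the
    pointwise 95% interval comes from ``n_draws`` seeded draws of the
    coefficient posterior.  With ``drying=True`` the sign is flipped to the
    drying direction (change in stem RWC per unit *decrease* in soil VWC),
    the convention used by the threshold scan.
    """
    grid = np.linspace(fit.x_min, fit.x_max, n_grid)
    Xd = _design(grid, fit.knots, deriv=1)
    deriv = Xd @ fit.coef
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.coef, fit.cov, size=n_draws, method="svd")
    dgrid = draws @ Xd.T
    lo = np.percentile(dgrid, 2.5, axis=0)
    hi = np.percentile(dgrid, 97.5, axis=0)
    if drying:
        deriv, lo, hi = -deriv, -hi, -lo
    return pd.DataFrame(
        {"soil_vwc": grid, "derivative": deriv, "ci_lower": lo, "ci_upper": hi}
    )


def detect_threshold(grid: pd.DataFrame, min_run: int = MIN_RUN) -> ThresholdResult:
    """Locate the sustained rapid-decline threshold on a derivative grid.

    ``grid`` must be ordered by ``soil_vwc`` and carry ``derivative``,
    ``ci_upper`` columns (drying-direction sign: negative = declining as the
    soil dries).  A point qualifies when its CI upper limit is below zero and
    its derivative lies within the strongest negative quartile (≤ the 25th
    percentile of all grid derivatives).  Scanning from the wet end toward
    dry, the threshold is the soil VWC of the first point opening a run of
    ≥ ``min_run`` consecutive qualifying points; absence is a valid result.
    """
    g = grid.sort_values("soil_vwc").reset_index(drop=True)
    deriv = g["derivative"].to_numpy(float)
    q25 = np.percentile(deriv, 25)
    sig = g["ci_upper"].to_numpy(float) < 0
    strong = deriv <= q25
    qual = sig & strong
    trace = g.assign(ci_below_zero=sig, strongest_quartile=strong, qualifying=qual)
    # walk wet → dry: descending soil VWC
    order = np.arange(len(g))[::-1]
    run_start = None
    for pos, idx in enumerate(order):
        if not qual[idx]:
            continue
        run = order[pos : pos + min_run]
        if len(run) == min_run and qual[run].all():
            run_start = idx
            break
    if run_start is None:
        return ThresholdResult(None, None, trace)
    return ThresholdResult(
        threshold_vwc=float(g.loc[run_start, "soil_vwc"]),
        qualifying_run=(int(run_start), int(run_start - min_run + 1)),
        criteria_trace=trace,
    )


def compare_groups(
    fit_palm: SmoothFit,
    fit_dicot: SmoothFit,
    pairs: pd.DataFrame,
    k: int = 6,
):
    """Approximate F-test of group-specific smooths against one pooled smooth.

    The pooled model is refitted on all pairs; the group model's residual sum
    of squares and effective degrees of freedom are the sums over the two
    per-group fits.  Returns ``(F, p)``; a near-zero statistic means the
    groups share one response curve.
    """
    if fit_palm.k != fit_dicot.k:
        raise ValueError("group fits must share the basis dimension")
    pooled = fit_smooth(pairs, "pooled", k=k)
    rss0, edf0 = pooled.rss, pooled.edf
    rss1 = fit_palm.rss + fit_dicot.rss
    edf1 = fit_palm.edf + fit_dicot.edf
    n = pooled.n_obs
    df_num = max(edf1 - edf0, 1e-8)
    df_den = n - edf1
    F = max(0.0, (rss0 - rss1) / df_num) / (rss1 / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return float(F), p


def soil_threshold_analysis(
    pairs: pd.DataFrame,
    k: int = 6,
    n_grid: int = 200,
    n_draws: int = 1000,
    seed: int | None = None,
):
    """Pooled fit → drying-direction derivative → threshold, in one call."""
    fit = fit_smooth(pairs, "pooled", k=k)
    grid = derivative_with_ci(fit, n_grid=n_grid, n_draws=n_draws, seed=seed, drying=True)
    return fit, grid, detect_threshold(grid)
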