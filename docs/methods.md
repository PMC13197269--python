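# Methods

This note documents the models, conventions and numerical choices behind
`stemwater`, and what the synthetic scenarios do and do not establish about
real field data.

## Calibration chain

FDR sensors report dielectric permittivity ε and stem temperature T_stem.
Water content follows the linear-in-√ε woody-tissue calibration
θ_stem = a·√ε + b (defaults a = 0.2227, b = −0.396 m³ m⁻³), then an
additive temperature correction θ_T = θ_stem + (T_stem − T_ref)·β with
T_ref = 25 °C and β = −0.000974 m³ m⁻³ °C⁻¹. ΔT is defined as
T_stem − T_ref exactly as the correction is usually stated, even though the
physical sign convention could be argued either way; users re-fitting a
sensor-specific calibration can override every coefficient.

Values outside [0, 1] are flagged but not clipped by default — silent
clipping would hide calibration misuse (clipping is available as an
option). Missing readings propagate; no interpolation happens at this
stage, because the daily-aggregation stage owns the gap policy.

The chain is exactly invertible (ε = ((θ_stem − b)/a)², θ_stem recovered
from θ_T at the known temperature); the inverse raises once θ_stem reaches
the intercept, where √ε would be non-positive. Round-trip accuracy is at
machine precision (tested at 1e−12).

## Percentile and day conventions

One percentile convention is used package-wide: linear interpolation
between order statistics (numpy's default). Turgid content θ_t is the 99th
percentile of the full series, θ_d the 1st; a day's high/low are the
within-day 99th/1st percentiles, so at 15-minute cadence (96 samples) the
daily high is effectively the nightly maximum. Days are calendar days in
local site time; a day must carry ≥80% of its expected samples to be
retained, which guards the within-day percentiles against gap bias.

RWC = θ/θ_t is not capped at 1; values slightly above 1 (θ above the 99th
percentile) are retained. They are excluded from strain statistics by the
RWC > 0.95 rule anyway.

A caveat worth knowing: the intuition "a day's range cannot exceed the
seasonal range" holds for physically plausible (smooth) series but is not
a theorem under the percentile convention — a single day's 99th percentile
trims fewer points than the full-series one, so heavy iid noise can invert
the order. The property test asserts it for realistic series only.

## Storage volumes

Palms lack secondary growth and conduct water through the whole
parenchyma-rich stem, so palm active storage is a full cylinder:
S = π·(DBH/2)²·H·θ. Dicot storage is confined to sapwood:
S = f·A_s·H·θ with tapering factor f = 0.5 and annulus area
A_s = π·((DBH/2)² − (DBH/2 − d)²) for sapwood depth d. When d is not
measured it comes from a user-configurable linear DBH allometry; the
shipped default (d = 0.159·DBH) is anchored at the worked example of a
3.5 cm depth at 0.22 m DBH and should be replaced with site-specific
coefficients when available.

## Strain classification and thresholds

Daily relative discharge capacity is the day's θ range as a percentage of
the tree's maximum diurnal discharge (99th percentile of daily ranges).
Strain bins are half-open, lower-inclusive: severe [0, 5)%, high [5, 10)%,
moderate [10, 20)%; boundary hits are measure-zero in practice. Days with
daily-max RWC > 0.95 are excluded from strain statistics because small
ranges at high hydration reflect water abundance, not impairment.

RWC_crit averages daily-max RWC over all non-excluded days below 10%
capacity (the "<10%" formula, not just the named high-strain bin). If a
tree never dropped below 10%, RWC_crit is right-censored and reported as
an upper bound "< RWC_min" with a machine-readable flag. RWC_mrc averages
days above 75% capacity over the *entire* record including high-hydration
days. RWC_min is the minimum of daily maxima (the driest hydration status
reached), configurable to the minimum of all samples.

The VPD check — Pearson r between daily-max VPD and capacity over stress
days (RWC ≤ 0.95) — separates atmospheric demand from plant regulation: a
weak or negative r indicates stomatal control of the discharge decline.
Correlations are computed on untransformed daily values with no lag
structure.

## Vapour pressure deficit

esat uses the Tetens formula, esat = 0.6108·exp(17.27·T/(T + 237.3)) kPa,
and VPD = esat·(1 − RH/100). Tetens is fully specified, standard in
agrometeorology, and agrees with the defaults of common eddy-flux
processing packages to well under a percent over tropical temperature
ranges; coefficient-level agreement with any particular package is not
claimed. Daily maximum VPD is the within-day 99th percentile under the
same day rules as the stem series.

## Soil-coupling smooth and breakpoint

Daily-max stem RWC is regressed on daily-max soil VWC (default depth label
"100cm") pooled across trees. The smooth is a penalized cubic B-spline
with k = 6 basis functions (evenly spaced interior knots), curvature
penalty ∫f″², and smoothing parameter λ selected by minimising the
profiled REML score; if that optimisation fails the package falls back to
GCV with a warning. k = 6 balances flexibility against overfitting for a
single monotone-with-knee response. Uncertainty uses the Gaussian
approximation to the coefficient posterior, β ~ N(β̂, σ²(XᵀX + λS)⁻¹) with
σ² the Pearson estimate on n − edf degrees of freedom. The implementation
is validated in the test suite against an independent REML GAM
implementation (R mgcv) to 4 decimals on a fixed fixture.

The first derivative is analytic (derivative of the basis); its pointwise
95% band comes from 1000 seeded posterior draws on a 200-point uniform
grid (both configurable — these sizes give stable quartile and CI
estimates). The fitted response declines as soil *dries*, so the
breakpoint scan uses the drying-direction derivative (−d/dVWC, negative in
the decline zone). A grid point qualifies when its CI upper limit is below
zero and its derivative lies within the strongest negative quartile (≤ the
25th percentile of grid derivatives); scanning from the wet end toward
dry, the threshold is the soil VWC of the first point opening a run of ≥5
consecutive qualifying points. No qualifying run means no threshold — a
valid, reported outcome. The rule is invariant to positive affine
rescaling of the response.

Group comparison (palm vs dicot response curves) uses an approximate
F-test of the two per-group smooths against a single pooled smooth, with
effective degrees of freedom in place of parameter counts. A full
random-smooth mixed-model structure is deliberately out of scope; per-tree
effects enter only through the per-tree RWC normalisation.

## Group inference

Two tests suited to tiny groups: a one-sample t of dicot values against
the palm group mean, and a permutation test on the difference in group
means. The permutation null enumerates all label arrangements exhaustively
whenever their count is at most the requested iterations (C(7,2) = 21 for
the default stand — exact at no cost); otherwise it draws seeded uniform
permutations. The observed arrangement is included in numerator and
denominator, guaranteeing p > 0; with 2-vs-5 groups the smallest
attainable p is 1/21 ≈ 0.048.

## Synthetic scenarios

The generator emulates a 163-day tropical dry-down at 15-minute cadence:
wet phase to day 20, drought to day 140, rewetting after. Defaults were
chosen once to mirror that setting — seven trees (2 palms, 5 dicots) with
group-level truths (palm θ_t 0.70, diurnal amplitude 0.048, critical RWC
0.68; dicot 0.41 / 0.018 / 0.81), soil starting at 0.29 m³ m⁻³ decaying
at 0.02 day⁻¹ toward a 0.10 floor with 0.0005 m³ m⁻³ mm⁻¹ rain recharge
(≈1 event/day of mean 8 mm in wet phases), stem temperature a shared
24–32 °C sinusoid, permittivity noise sd 0.01 (≈2×10⁻⁴ m³ m⁻³ in θ, an
instrument-level noise floor), and a refill cutoff at soil VWC 0.19.

Per tree and day, the nightly-max θ targets the turgid value while
daily-max soil VWC exceeds the refill cutoff; below it the target falls
toward the dry value along a sharp exponential knee (width 0.015 m³ m⁻³,
matching the abrupt transitions such sensors record), and the stem state
relaxes toward the target with a 1-day time constant, which also produces
gradual rehydration after rain pulses. The diurnal discharge sinusoid
(pre-dawn peak, early-afternoon trough) is scaled by a sigmoid of daily
RWC (width 0.01, floor 1%) that collapses below the tree's critical RWC.
θ is converted to permittivity through the exact calibration inverse at
the simulated stem temperature before noise is added. All randomness
derives from one seeded generator with per-tree spawned streams, so equal
seed and configuration give bit-identical output.

What the scenarios establish: that the pipeline recovers embedded truths —
θ_t within ±0.01, diurnal amplitude within ±15%, critical RWC within
±0.05, refill cutoff within ±0.02 m³ m⁻³ — under realistic noise on the
full 163-day design (verified over 25 seeds). What they do not establish:
behaviour under sensor drift, installation artefacts, missing-data bursts,
species-level response diversity, hysteresis or time-lagged soil–stem
coupling, none of which the generator attempts to emulate. The critical-
RWC estimator in particular inherits a small negative bias (≈0.03) because
sub-10%-capacity days necessarily sit below the shut-down midpoint.

## Reference table

`stemwater.datasets.amazon_drydown()` ships the per-tree summary of a
published 163-day Amazonian monitoring campaign (2 palms, 5 subcanopy
dicots) used by the worked examples and the acceptance script. Two of its
arithmetic quirks are worth noting: the printed palm diurnal-Δθ sd (0.015)
differs from the exact two-value sample sd (0.0141) by rounding, and the
table's dry-value percentile is labelled "0.01st" in some sources while
the 1st percentile is used throughout here (a configurable override
exists).
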