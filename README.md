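# stemwater

Analysis of continuous stem water content in trees and palms measured with
frequency-domain reflectometry (FDR) sensors. The package is aimed at plant
ecophysiologists monitoring stem hydration through drought: it turns raw
per-tree permittivity/temperature series, soil moisture profiles and basic
meteorology into storage statistics, hydraulic-strain thresholds, and
soil-moisture breakpoints, with a synthetic-scenario generator for testing
every stage against known ground truth.

## What it computes

**Calibration.** Volumetric stem water content from dielectric permittivity,
θ_stem = 0.2227·√ε − 0.396 (a general woody-tissue calibration; coefficients
configurable), corrected to a 25 °C reference with θ_T = θ_stem +
ΔT_stem·β, β = −0.000974 °C⁻¹. The chain is exactly invertible, which the
scenario generator uses to synthesise raw sensor readings.

**Storage metrics.** Per tree: turgid water content θ_t (seasonal 99th
percentile), dry value θ_d (1st percentile), seasonal Δθ = θ_t − θ_d, water
deficit (θ_t − θ_d)/θ_t·100, diurnal Δθ (99th percentile of within-day
ranges), and active storage S — whole-stem cylinder volume × θ for palms,
tapered sapwood volume f·A_s·H·θ (f = 0.5) for dicots.

**Hydraulic strain.** Daily relative discharge capacity (a day's θ range as
% of the tree's diurnal Δθ) classed as moderate (10–20%), high (5–10%) or
severe (<5%) strain; days with daily-max RWC > 0.95 are excluded. RWC_crit
is the mean daily-max RWC over sub-10%-capacity days (censored as "< x"
when the tree never got there); RWC_mrc the mean over >75%-capacity days on
the full record.

**Soil coupling.** Daily-max stem RWC is regressed on daily-max soil VWC
with a penalized cubic regression spline (k = 6 basis functions, REML
smoothing selection — cross-checked against R's mgcv). The smooth's first
derivative with simulated 95% CIs locates the soil moisture below which
stem reserves enter a sustained rapid-decline zone: the first grid point
(scanning wet→dry) opening a run of ≥5 points whose CI excludes zero and
whose derivative sits in the strongest-negative quartile.

**Inference.** Palm-vs-dicot contrasts by one-sample t-test of dicot values
against the palm mean and by permutation of group labels (difference in
means, 5000 iterations, exhaustive enumeration when the label arrangements
are few).

## Worked example

```python
import stemwater as sw
from stemwater.datasets import amazon_drydown

table = amazon_drydown()          # 2 palms + 5 dicots, 163-day dry-down
(pm, psd), (dm, dsd) = sw.group_means(table["theta_t"], table["group"])
print(f"turgid water content: palms {pm:.3f} ± {psd:.3f}, "
      f"dicots {dm:.3f} ± {dsd:.3f} m3/m3")
t, p = sw.one_sample_t(table.loc[table.group == 'dicot', 'theta_t'], pm)
print(f"one-sample t: t = {t:.2f}, p = {p:.2g}")

palm = sw.TreeSpec("palm", "palm", height=13.0, dbh=0.22)
print(f"active storage: {sw.active_storage(palm, 0.728):.2f} m3")
```

prints

```
turgid water content: palms 0.701 ± 0.039, dicots 0.411 ± 0.058 m3/m3
one-sample t: t = -11.08, p = 0.00038
active storage: 0.36 m3
```

i.e. palms hold a ~70% larger turgid water content than co-occurring
dicots (highly significant despite n = 2 vs 5), and a 13-m palm of 0.22 m
DBH stores about 360 L of physiologically active water in its stem.

A full synthetic pipeline run from the shell:

```
stemwater simulate --n-days 163 --seed 1 --out scenario/
stemwater metrics scenario/sensor.csv --out metrics.csv
stemwater soil-threshold scenario/sensor.csv scenario/soil.csv --out threshold.json
```

The default scenario embeds a refill cutoff at soil VWC 0.19 m³ m⁻³; the
detected threshold lands within ±0.02 of it.

## Layout

- `stemwater.calibration` — permittivity → θ chain and its inverse
- `stemwater.meteorology` — Tetens VPD, daily maxima
- `stemwater.hydration` — percentile conventions, daily summaries, storage
- `stemwater.strain` — capacity, strain classes, RWC_crit / RWC_mrc
- `stemwater.soil` — penalized-spline smooths, derivatives, breakpoints
- `stemwater.inference` — group contrasts
- `stemwater.synthetic` — scenario generator with embedded ground truth
- `stemwater.io` / `stemwater.cli` — CSV formats, pipeline, CLI

See `docs/methods.md` for the modelling and numerical choices.
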