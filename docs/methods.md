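# Methods

This note documents the model implemented by `ecoclim`, its default
parameters, the synthetic-data generator, and the main design choices.

## 1. Climate preprocessing

Input is a grid of cells, each with 12 monthly normals: `tmin`, `tmax`
(°C) and `precip` (mm/month). `tavg = (tmin + tmax) / 2`.

Monthly values are treated as point estimates anchored at mid-month on a
365-day calendar and interpolated to daily values with periodic linear
interpolation (the cycle wraps December→January). Daily values are then
aggregated to 52 weeks: weeks 1–51 cover 7 days each; week 52 covers the
remaining 8 days (days 357–365). Temperatures are weekly means;
precipitation is the weekly sum of the daily rate. Linear interpolation
between mid-month anchors conserves structure exactly for constant fields
and keeps annual precipitation within ~2% of the monthly totals (verified
in tests); weekly bin means (rather than midpoint sampling) were chosen so
that constant inputs are preserved exactly and no daily information is
discarded.

## 2. Growth indices

Both responses are trapezoids with corner points `(a, b, c, d)`:
0 below `a` and above `d`, 1 between `b` and `c`, linear in between.

- Temperature index `TI(tavg)` over `DV0..DV3`.
- Moisture index `MI(sm)` over `SM0..SM3`, where `sm` is the weekly soil
  moisture from the bucket model (unitless fraction of capacity).

The weekly growth index is `GI_w = TI_w * MI_w` and the annual growth index
`GI_A` is the mean of `GI_w` over the 52 weeks.

## 3. Soil-moisture bucket

Weekly potential evapotranspiration (mm/week) is

```
PET_w = pet_coeff * max(0, 0.46 * tavg_w + 8.13)
```

a linearized temperature-driven form (Blaney–Criddle-like). The bucket
updates as

```
sm_w = clamp(sm_prev + (P_w - PET_w) / capacity, 0, sm_cap)
```

with `capacity = 100 mm`, `sm_cap = 4` (transient storage up to 4×
capacity, representing flooding). **Year-to-year carryover is capped at
field capacity:** the value carried into week 1 of the next cycle is
`min(sm_52, 1)`, representing drainage/runoff of the above-capacity
surplus at annual scale. Without this cap, any cell with annual
precipitation exceeding annual PET accumulates moisture without bound
until `sm = 4` everywhere year-round, which makes every humid cell
permanently waterlogged (wet stress saturates) and leaves no suitable area
anywhere — the carryover cap is the minimal change that preserves both the
weekly flooding dynamics and the existence of suitable mid-latitude bands.

The cycle is spun up from `sm_init = 0.5` and iterated until the annual
cycle converges (`max |Δ| < 1e-6` between successive years), with a hard
limit of 100 years; non-convergence raises `ConvergenceError` carrying the
residual. Convergence is guaranteed in practice because the clamp makes
the map a contraction; tests verify the converged cycle is independent of
`sm_init`.

## 4. Stress indices

Each stress (cold CS, heat HS, dry DS, wet WS) accumulates weekly
exceedances beyond a threshold, scaled by a species rate, annualized, and
saturated at 1:

```
S = min(1, 52 * |rate| * sum_w exceedance_w)
```

with exceedances

| stress | exceedance |
| --- | --- |
| cold | `max(0, TTCS - tmin_w)` |
| heat | `max(0, tmax_w - TTHS)` |
| dry  | `max(0, SMDS - sm_w)` |
| wet  | `max(0, sm_w - SMWS)` |

## 5. Ecoclimatic index and classification

```
EI = 100 * GI_A * (1 - CS)(1 - HS)(1 - DS)(1 - WS)
```

Classes: `unsuitable` if `EI < 1e-9` (numerical zero), `high` if
`EI >= 30`, otherwise `suitable`.

## 6. Default parameters (*Brassica napus*)

Shipped in `src/ecoclim/data/brassica_napus.yaml`:

| parameter | value | low | high | meaning |
| --- | --- | --- | --- | --- |
| DV0 | 5 °C | 4 | 6 | lower temperature limit |
| DV1 | 10 °C | 9 | 11 | lower optimum |
| DV2 | 23 °C | 22 | 24 | upper optimum |
| DV3 | 27 °C | 26 | 28 | upper limit |
| SM0 | 0.1 | 0.09 | 0.11 | lower moisture limit |
| SM1 | 0.2 | 0.18 | 0.22 | lower optimum |
| SM2 | 0.8 | 0.72 | 0.88 | upper optimum |
| SM3 | 2.5 | 2.25 | 2.75 | upper limit |
| TTCS | 1 °C | 0.9 | 1.1 | cold-stress threshold |
| THCS | −0.00009 | −0.000081 | −0.000099 | cold-stress rate |
| TTHS | 27 °C | 26 | 28 | heat-stress threshold |
| THHS | 0.001 | 0.0009 | 0.0011 | heat-stress rate |
| SMDS | 0.1 | 0.09 | 0.11 | dry-stress threshold |
| HDS | −0.005 | −0.0045 | −0.0055 | dry-stress rate |
| SMWS | 2.5 | 2.25 | 2.75 | wet-stress threshold |
| HWS | 0.002 | 0.0018 | 0.0022 | wet-stress rate |

Perturbation bounds are ±1 °C for the temperature corner points and TTHS,
and ±10% otherwise; the YAML may override any bound explicitly. Hydrology
constants (`soil_capacity = 100 mm`, `sm_init = 0.5`, `sm_cap = 4`,
`pet_coeff = 1`) are model settings, not species parameters, and are not
perturbed.

## 7. Occurrence cleaning

Three sequential stages, each recorded in a `CleaningReport` whose counts
must satisfy `retained = initial − no_coords − duplicates − thinned`:

1. drop records missing either coordinate;
2. deduplicate on coordinates rounded to 4 decimals, keeping the first
   record in `(source, record_id)` order;
3. greedy sequential spatial thinning: scan records in order, keep a
   record only if it lies ≥ 50 km (haversine, Earth radius 6371.0088 km)
   from every record already kept.

The greedy rule guarantees all retained pairs are ≥ 50 km apart and every
removed record is within 50 km of some retained record (verified against a
brute-force O(n²) oracle in tests).

Validation overlays cleaned records on model output by nearest grid cell
(ties broken by lowest cell id; records farther than the grid diagonal
from any cell are rejected) and reports the percentage of records per
suitability class.

## 8. Sensitivity analysis

One-at-a-time: each of the 16 species parameters is set to its low and its
high bound while all others stay central — 32 runs plus the baseline.
For each run the cosine-latitude-weighted area of each suitability class
is compared with the baseline as a percent change (undefined, reported as
null, when the baseline area is zero). A parameter is labelled *sensitive*
when any class area changes by ≥ 2% in either direction; both directions
of a parameter are flagged together.

Because perturbations never touch the hydrology constants, the weekly
series and converged soil-moisture cycle are computed once per cell and
reused across all 33 evaluations (`prepare_cell` / `evaluate_cell`).

## 9. Scenario comparison

Given baseline and future results on the same cells, each cell gets
`ΔEI` and per-stress deltas, plus a transition label from its class pair:
`stable_*`, `gained` (unsuitable→suitable/high), `lost` (→unsuitable),
`upgraded` (suitable→high), `downgraded` (high→suitable). With two
futures, the agreement map labels each cell `both_increase`,
`both_decrease`, `both_no_change` (both |ΔEI| ≤ 1 by default) or
`disagree`. Stress tallies count cells with increase/decrease/no-change
per stress, using a 0.01 tolerance on the delta.

## 10. Synthetic-data generator

The generator builds a zonally symmetric idealized planet:

- `tavg(lat, month) = 27 − 0.55·|lat| + A(lat)·cos(2π(m − peak)/12)` with
  seasonal amplitude `A = 2 + 0.25·|lat|`; the seasonal peak is July in
  the northern hemisphere, January in the southern. Diurnal range is 8 °C
  (`tmin/tmax = tavg ∓ 4`).
- Precipitation is 80 mm/month with a summer wet season (amplitude 0.5 of
  base) and a subtropical arid band at |lat| ∈ [12, 28] where
  precipitation is multiplied by 0.2.
- Optional Gaussian noise (`noise_sd`, seeded) on temperatures and
  precipitation; off by default so structural tests are exact.

Under the default *B. napus* parameters this produces one contiguous
high-suitability band per hemisphere near |lat| ≈ 28–33°, heat/dry-limited
equatorward and cold-limited poleward.

Futures apply uniform warming (optionally latitude-dependent), a
precipitation scale factor, and optional seeded model noise.

Occurrences are sampled over cells with `EI > 0` with probability ∝
`EI^gamma`, jittered uniformly within the cell, then contaminated to
exercise the cleaning pipeline: a Bernoulli fraction of blanked
coordinates, exact duplicate copies, and tight clusters (points within
20 km of a parent record).

**Generator limitations.** The world is zonally symmetric with no
continents, orography, ocean effects or interannual variability; the arid
band is a hard-edged box; precipitation seasonality is a single harmonic.
It is designed to exhibit the qualitative structure the model predicts
(mid-latitude bands, poleward shift under warming), not to emulate any
real climatology.

Analytic fixtures (`fixture_weekly` / `fixture_cell`) provide flat-profile
cells with known outcomes: `optimal` (EI exactly 100, with precipitation
balancing annual PET), `cold`, `hot`, `dry` (EI 0) and `wet` (small
positive EI under wet stress).

## 11. Design choices

- **Library + examples + thin CLI.** The substance lives in importable,
  testable modules; `examples/` holds narrative walkthroughs; the CLI is a
  thin click wrapper because the workflow is a natural file-in/file-out
  pipeline.
- **Provenance headers.** Every output CSV carries `#`-prefixed comments
  (package version, seed, input SHA-256 prefixes) and remains readable
  with `pandas.read_csv(..., comment="#")`.
- **Frozen dataclasses with validating constructors** for all value types
  (parameters, normals, results, reports), so invalid states are
  unrepresentable and errors name the offending field/cell/month.
- **Determinism.** All stochastic steps take explicit seeds via
  `numpy.random.default_rng`; identical seeds give byte-identical outputs.
- **Errors.** Domain errors raise typed exceptions
  (`ParameterError`, `ClimateDataError`, `ConvergenceError`); the CLI maps
  them to `ecoclim error: ...` on stderr with exit code 1.
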