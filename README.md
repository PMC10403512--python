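# ecoclim

A weekly growth/stress ecoclimatic suitability model for *Brassica napus*
(oilseed rape), with tools for occurrence-record cleaning, validation
overlays, one-at-a-time parameter sensitivity analysis, climate-change
scenario comparison, and a synthetic-climate generator for testing and
demonstration.

## The scientific problem

Where can a plant species persist, given only long-term climate normals?
Process-oriented niche models of the CLIMEX family answer this by combining
two opposing annual signals per location:

- **Growth.** In each week of an average year, conditions support growth to
  the degree that temperature and soil moisture fall inside the species'
  favourable range. The annual growth index `GI_A` is the mean over 52 weeks
  of the product of a temperature index and a moisture index, each a
  trapezoidal response with species-specific corner points.
- **Stress.** Outside the favourable season, the species accumulates cold,
  heat, dry and wet stress at species-specific rates proportional to how far
  weekly conditions exceed a threshold. Each annual stress index saturates
  at 1 (lethal).

These combine into the **Ecoclimatic Index**

```
EI = 100 * GI_A * (1 - CS)(1 - HS)(1 - DS)(1 - WS)
```

on a 0–100 scale, classified as *unsuitable* (EI ≈ 0), *suitable*
(0 < EI < 30) or *high* (EI ≥ 30). Soil moisture is modelled with a simple
weekly bucket (precipitation in, temperature-driven potential
evapotranspiration out), spun up to its annual cycle. Monthly climate
normals are interpolated to daily values and aggregated to 52 weeks.

The package ships a parameter set for oilseed rape, a widely grown
temperate crop that is heat- and drought-limited toward the equator and
cold-limited toward the poles, so its suitable area forms mid-latitude
bands — a structure the synthetic generator reproduces and the test suite
verifies.

## Worked example

The `ecoclim` command chains the whole pipeline. Generate a synthetic
planet, map suitability, then clean and validate occurrence records sampled
from the model's own suitability surface:

```
$ ecoclim synth --out-dir demo --n-lat 24 --n-lon 12 --lat-min -60 --lat-max 60 \
      --noise-sd 0.3 --seed 1 --occurrences 2000
wrote demo/climate.csv (288 cells, seed 1)
wrote demo/occurrences.csv (2300 records, seed 1)

$ ecoclim run --climate demo/climate.csv --out demo/ei.csv --summary demo/summary.json
wrote demo/ei.csv (288 cells)
wrote demo/summary.json

$ ecoclim clean --occurrences demo/occurrences.csv --out demo/cleaned.csv \
      --report demo/clean_report.json
wrote demo/cleaned.csv (1532 of 2300 records retained)
wrote demo/clean_report.json

$ ecoclim validate --occurrences demo/cleaned.csv --ei demo/ei.csv \
      --report demo/validation.json
wrote demo/validation.json (99.8% of records in suitable-or-high cells)
```

Every output CSV starts with a provenance header, e.g.:

```
# ecoclim 0.1.0
# input climate: demo/climate.csv sha256:4ad2cf7059df708d
cell_id,lat,lon,gi_a,cs,hs,ds,ws,ei,class
c000_000,-57.5,-165.0,0.17808577434470724,1.0,0.0,0.0,0.0,0.0,unsuitable
```

The same pipeline through the Python API (`python examples/run_pipeline.py`)
prints:

```
generated 288 grid cells
cosine-weighted class-area shares:
  unsuitable  83.5%
  suitable     9.4%
  high         7.1%
best cell: c005_011 at lat -32.5  EI=32.1

cleaning: 2300 raw -> 1532 retained (-208 no coords, -100 duplicates, -460 thinned)
validation overlay (percent of records per class):
  unsuitable   0.2%
  suitable    20.6%
  high        79.2%
```

Sensitivity (`ecoclim sensitivity` or `examples/sensitivity_analysis.py`)
perturbs each of the 16 species parameters to its low and high value —
32 model runs — and reports percent changes in class areas; a parameter is
flagged *sensitive* when any class area shifts by ≥ 2%. Scenario comparison
(`ecoclim scenario` or `examples/scenario_comparison.py`) contrasts a
baseline with one or two future climates, labelling per-cell transitions
(gained / lost / upgraded / downgraded / stable) and, with two futures, an
agreement map. From the example script, under a +2 °C future:

```
transitions under future 1 (+2 degC):
  gained             24 cells
  stable_high        24 cells
  stable_suitable    24 cells
  stable_unsuitable  216 cells

stress-change tallies (future 1 vs baseline):
  cs: +0 cells up, -96 down, 192 unchanged
  hs: +49 cells up, -0 down, 239 unchanged
  ds: +48 cells up, -0 down, 240 unchanged
  ws: +0 cells up, -0 down, 288 unchanged
```

Warming relaxes cold stress at the poleward margin (cells *gained*) while
heat and dry stress intensify toward the equator — the expected poleward
shift.

## Library layout

| Module | Contents |
| --- | --- |
| `ecoclim.params` | `SpeciesParameters`, `PerturbationTable`, YAML loading |
| `ecoclim.climate_grid` | monthly normals, grids, monthly→weekly interpolation, CSV I/O |
| `ecoclim.engine` | trapezoid indices, soil-moisture bucket, stress accumulation, `run_grid` |
| `ecoclim.occurrences` | record cleaning (missing coords, duplicates, 50 km thinning), validation overlay |
| `ecoclim.sensitivity` | one-at-a-time perturbation experiment, cosine-weighted class areas |
| `ecoclim.scenario` | baseline/future deltas, transitions, agreement maps, stress tallies |
| `ecoclim.synthetic` | synthetic climate/occurrence generators, analytic test fixtures |
| `ecoclim.cli` | the `ecoclim` command |

See `docs/methods.md` for the full model description, parameter defaults
and design notes.

## Reproduction

```
pip install --no-build-isolation -e .[test]
pytest -q tests/                                   # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script runs the complete pipeline on a seeded synthetic
world and writes every headline quantity (class-area shares, cleaning
counts, validation share, sensitivity summary, scenario tallies) as JSON.
All randomness is controlled by explicit seeds; reruns with the same seed
are byte-identical.
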