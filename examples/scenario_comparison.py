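"""Climate-change comparison: run the model under a baseline and a +2 degC
future, classify per-cell transitions, and compare two future realizations
with an agreement map.

Run with:  python examples/scenario_comparison.py
"""

from collections import Counter

from ecoclim import (
    ClimateGenConfig,
    ScenarioGenConfig,
    agreement_map,
    ei_change,
    generate_climate,
    generate_future,
    load_parameters,
    run_grid,
    stress_change_summary,
)

params, _ = load_parameters()
grid = generate_climate(
    ClimateGenConfig(n_lat=24, n_lon=12, lat_range=(-60, 60), seed=1)
)
baseline = run_grid(grid, params)

# Two +2 degC futures differing only in model noise (two "GCMs").
futures = [
    generate_future(grid, ScenarioGenConfig(warming=2.0, model_noise_sd=0.3, seed=s))
    for s in (101, 202)
]
changes = [ei_change(baseline, run_grid(f, params)) for f in futures]

print("transitions under future 1 (+2 degC):")
for label, n in sorted(Counter(c.transition for c in changes[0]).items()):
    print(f"  {label:16s} {n:4d} cells")

print("\nstress-change tallies (future 1 vs baseline):")
summary = stress_change_summary(changes[0])
for stress, tallies in summary.items():
    print(f"  {stress}: +{tallies['increase']} cells up, "
          f"-{tallies['decrease']} down, {tallies['no_change']} unchanged")

agreement = agreement_map(changes[0], changes[1], tol_ei=1.0)
print("\nagreement between the two futures:")
for label, n in sorted(Counter(a.category for a in agreement).items()):
    print(f"  {label:16s} {n:4d} cells")
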