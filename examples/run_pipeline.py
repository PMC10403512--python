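"""End-to-end walkthrough: synthetic world -> suitability map -> occurrence
cleaning -> validation overlay.

Run with:  python examples/run_pipeline.py
"""

from ecoclim import (
    ClimateGenConfig,
    class_area,
    clean_pipeline,
    generate_climate,
    generate_occurrences,
    load_parameters,
    overlay_validation,
    run_grid,
)

params, _ = load_parameters()  # packaged oilseed-rape parameter set

# 1. A small synthetic planet: 24 latitude bands x 12 longitudes.
grid = generate_climate(
    ClimateGenConfig(n_lat=24, n_lon=12, lat_range=(-60, 60), noise_sd=0.3, seed=1)
)
print(f"generated {len(grid)} grid cells")

# 2. Weekly growth/stress model for every cell.
results = run_grid(grid, params)
areas = class_area(results)
total = sum(areas.values())
print("cosine-weighted class-area shares:")
for cls in ("unsuitable", "suitable", "high"):
    print(f"  {cls:10s} {100 * areas[cls] / total:5.1f}%")

best = max(results, key=lambda r: r.ei)
print(f"best cell: {best.cell_id} at lat {best.lat:+.1f}  EI={best.ei:.1f}")

# 3. Sample occurrences from the EI surface, with realistic contamination.
records = generate_occurrences(
    results, n=2000, gamma=4.0, frac_missing=0.1, frac_duplicate=0.05,
    frac_cluster=0.1, seed=1,
)
kept, report = clean_pipeline(records)
print(f"\ncleaning: {report.n_initial} raw -> {report.n_retained} retained "
      f"(-{report.n_removed_no_coords} no coords, "
      f"-{report.n_removed_duplicates} duplicates, "
      f"-{report.n_removed_thinning} thinned)")

# 4. Overlay the cleaned records on the suitability map.
shares = overlay_validation(kept, results)
print("validation overlay (percent of records per class):")
for cls, pct in shares.items():
    print(f"  {cls:10s} {pct:5.1f}%")
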