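"""Project suitability under warming and quantify how it shifts.

Fits the ensemble on the historical landscape, applies a uniform +4 C
scenario to every temperature layer, and summarizes the change in
suitability-weighted area, mean elevation and mean northing of the
suitable domain, plus the per-cell transition classes.
"""

from shapely.geometry import box

from ecoshift import (
    EnsembleConfig,
    GridSpec,
    SamplingConfig,
    TruthModel,
    assemble_table,
    build_envelope,
    classify_transitions,
    draw_pseudo_absences,
    fit_ensemble,
    generate_bioclim,
    generate_occurrences,
    generate_terrain,
    apply_scenario,
    northing_layer,
    pixel_area,
    predict_raster,
    summarize_shifts,
    warming_scenario,
)

grid = GridSpec(50, 50, 4000.0, origin_x=300_000.0, origin_y=4_200_000.0)
stack = generate_bioclim(generate_terrain(grid, seed=1), seed=2)
truth = TruthModel.calibrated("demo_montane_woodland",
                              {"bio5": -5.0, "elevation": 3.5}, stack,
                              prevalence=0.15)
occ = generate_occurrences(truth, stack, n_plots=800, seed=3)
config = SamplingConfig(n_pseudo=1000, seed=4)
pa = draw_pseudo_absences(build_envelope(occ, box(*grid.extent), config), config)
table = assemble_table(occ, pa, stack, config)
model = fit_ensemble(table, seed=5, config=EnsembleConfig.fast())

scenario = warming_scenario("SYN-GCM1", "ssp370", "2041-2060", delta_t=4.0)
future_stack = apply_scenario(stack, scenario, seed=6)

surfaces = {
    "historical": predict_raster(model, stack, truth.ecosystem_id),
    scenario.label: predict_raster(model, future_stack, truth.ecosystem_id),
}
summary = summarize_shifts(truth.ecosystem_id, surfaces, stack["elevation"],
                           pixel_area(grid), northing_layer(grid))[0]

print(f"scenario: {summary.scenario} (suitability cutoff "
      f"{summary.threshold_used})")
print(f"suitability-weighted area: {summary.area_hist:,.0f} -> "
      f"{summary.area_future:,.0f} km2  ({summary.pct_area_diff:+.1f}%)")
print(f"mean suitable elevation:   {summary.mean_elev_hist:,.0f} -> "
      f"{summary.mean_elev_future:,.0f} m   ({summary.pct_elev_diff:+.1f}%)")
print(f"mean suitable northing:    {summary.mean_northing_hist:,.0f} -> "
      f"{summary.mean_northing_future:,.0f} m "
      f"({summary.pct_northing_diff:+.2f}%)")

trans = classify_transitions(surfaces["historical"], surfaces[scenario.label])
counts = trans.counts()
total = sum(counts.values())
print("transition classes (fraction of cells):")
for name, n in counts.items():
    print(f"  {name:<18} {n / total:.2%}")
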