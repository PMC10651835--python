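"""From presence-only plots to a labelled training table.

Samples field plots from a known truth, screens the ecosystem for enough
distinct-cell records, builds the 100-km buffer envelope, drops uniform
pseudo-absences inside it, and assembles the deduplicated, stratified
table the models are fit on.
"""

from shapely.geometry import box

from ecoshift import (
    GridSpec,
    SamplingConfig,
    TruthModel,
    assemble_table,
    build_envelope,
    draw_pseudo_absences,
    filter_ecosystem,
    generate_bioclim,
    generate_occurrences,
    generate_terrain,
)

grid = GridSpec(50, 50, 4000.0, origin_x=300_000.0, origin_y=4_200_000.0)
stack = generate_bioclim(generate_terrain(grid, seed=1), seed=2)
truth = TruthModel.calibrated("demo_montane_woodland",
                              {"bio5": -5.0, "elevation": 3.5}, stack,
                              prevalence=0.15)

occ = generate_occurrences(truth, stack, n_plots=800, seed=3)
config = SamplingConfig(n_pseudo=1000, seed=4)
accepted, n_cells = filter_ecosystem(occ, grid, config)
print(f"presence plots:            {len(occ)} in {n_cells} distinct cells "
      f"(screen >= {config.min_presences}: {'pass' if accepted else 'fail'})")

envelope = build_envelope(occ, box(*grid.extent), config)
print(f"envelope area:             {envelope.area / 1e6:,.0f} km2 "
      f"(union of {config.buffer_radius_km:.0f}-km buffers, clipped)")

pa = draw_pseudo_absences(envelope, config)
table = assemble_table(occ, pa, stack, config)
n1 = int((table.df.label == 1).sum())
n0 = int((table.df.label == 0).sum())
print(f"table rows (one per cell): {len(table.df)} = {n1} presence + "
      f"{n0} pseudo-absence")
print(f"train/test split:          {len(table.train)}/{len(table.test)} "
      f"(stratified {config.train_fraction:.0%})")
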