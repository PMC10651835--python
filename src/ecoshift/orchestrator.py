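"""End-to-end seeded runs: configuration, artifacts, run manifest.

:func:`run_experiment` executes the full synthetic pipeline — landscape,
occurrences, training table, RFE + ensemble, evaluation, scenario
projection, shift summaries and zonal/uncertainty summaries — writing
every artifact under one output directory together with a manifest
(config hash, derived stage seeds, file checksums). A run is a pure
function of its :class:`RunConfig`: rerunning with the same config
reproduces the checksums of all deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .evaluation import evaluate_model, permutation_importance
from .geoprep import GridSpec, northing_layer, pixel_area, write_stack, write_ascii_grid
from .sampling import SamplingConfig, assemble_table, build_envelope, \
    draw_pseudo_absences, filter_ecosystem
from .sdm_ensemble import EnsembleConfig, RFEConfig, fit_ensemble, \
    predict_raster, run_rfe
from .shifts import DEFAULT_SUITABILITY_THRESHOLD, shift_summaries_frame, \
    summarize_shifts
from .synthgrid import ScenarioSpec, TruthModel, apply_scenario, \
    generate_bioclim, generate_occurrences, generate_properties, \
    generate_terrain, warming_scenario
from .zonal import multi_scenario_uncertainty, summarize_properties, \
    write_properties_geojson

logger = logging.getLogger("ecoshift")

__all__ = ["RunConfig", "run_experiment", "demo_config", "demo"]


@dataclass
class RunConfig:
    """Everything a run depends on; serializable and hashable."""

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 4000.0
    origin_x: float = 300_000.0
    origin_y: float = 4_400_000.0
    truths: list[TruthModel] = field(default_factory=list)
    n_plots: int = 800
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    rfe: RFEConfig = field(default_factory=RFEConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    scenarios: list[ScenarioSpec] = field(default_factory=list)
    threshold: float = DEFAULT_SUITABILITY_THRESHOLD
    threshold_overrides: dict = field(default_factory=dict)
    n_properties: int = 12
    n_permutations: int = 35
    master_seed: int = 0
    out_dir: str = "ecoshift_run"

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size,
                        self.origin_x, self.origin_y, "projected")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # mappings inside frozen dataclasses may be non-plain; normalize
        return json.loads(json.dumps(d, default=lambda o: dict(o)))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where a run lands is not what it computes
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(master_seed).generate_state(n) % (2**31)]


def run_experiment(config: RunConfig) -> dict:
    """Run the pipeline end to end; returns the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid
    truths = config.truths or [
        TruthModel("synthetic_montane_woodland",
                   {"bio5": -6.5, "elevation": 5.5}, intercept=-12.0)
    ]
    seeds = _stage_seeds(config.master_seed, 6 + 2 * len(truths))
    terrain_seed, clim_seed, props_seed, scen_seed = seeds[:4]
    eco_seeds = seeds[6:]

    artifacts: dict[str, str] = {}
    notes: list[str] = []

    def record(key: str, path: Path) -> None:
        artifacts[key] = str(path.relative_to(out))

    def stage(name):
        logger.info("stage=%s elapsed=%.1fs", name, time.time() - t0)

    # --- landscape -------------------------------------------------------
    stage("landscape")
    elevation = generate_terrain(grid, seed=terrain_seed)
    stack = generate_bioclim(elevation, seed=clim_seed)
    record("stack_historical", write_stack(stack, out / "stack_historical"))
    area_layer = pixel_area(grid)
    northing = northing_layer(grid)

    # --- scenario stacks -------------------------------------------------
    scenario_stacks = {}
    for i, spec in enumerate(config.scenarios):
        scenario_stacks[spec.label] = apply_scenario(stack, spec,
                                                     seed=scen_seed + i)
        record(f"stack_{spec.label}",
               write_stack(scenario_stacks[spec.label], out / f"stack_{spec.label}"))
    if not config.scenarios:
        notes.append("no scenarios configured; shift and zonal stages skipped")

    # --- properties ------------------------------------------------------
    props = generate_properties(grid, config.n_properties, seed=props_seed)
    ppath = out / "properties.geojson"
    write_properties_geojson(props, ppath)
    record("properties", ppath)

    study_area = box(*grid.extent)
    metrics_all = {}
    shift_frames = []
    zonal_frames = []

    for k, truth in enumerate(truths):
        eco = truth.ecosystem_id
        occ_seed, model_seed = eco_seeds[2 * k], eco_seeds[2 * k + 1]
        stage(f"sampling:{eco}")
        occ = generate_occurrences(truth, stack, config.n_plots, seed=occ_seed)
        opath = out / f"occurrences_{eco}.csv"
        occ.to_csv(opath, index=False)
        record(f"occurrences_{eco}", opath)
        accepted, n_cells = filter_ecosystem(occ, grid, config.sampling)
        if not accepted:
            raise RuntimeError(
                f"stage sampling:{eco} failed: {n_cells} distinct presence "
                f"cells < {config.sampling.min_presences}"
            )
        envelope = build_envelope(occ, study_area, config.sampling)
        pa = draw_pseudo_absences(envelope, config.sampling, seed=occ_seed + 1)
        scfg = dataclasses.replace(config.sampling, seed=occ_seed + 2)
        table = assemble_table(occ, pa, stack, scfg)
        tpath = out / f"training_{eco}.csv"
        table.save(tpath)
        record(f"training_{eco}", tpath)

        stage(f"model:{eco}")
        rfe_result = run_rfe(table, seed=model_seed, config=config.rfe)
        rfe_df = pd.DataFrame(
            sorted(rfe_result.rmse_by_size.items()),
            columns=["subset_size", "cv_rmse"],
        )
        rpath = out / f"rfe_{eco}.csv"
        rfe_df.to_csv(rpath, index=False)
        record(f"rfe_{eco}", rpath)
        model = fit_ensemble(table, rfe_result.selected, seed=model_seed,
                             config=config.ensemble)
        record(f"model_{eco}", model.save(out / f"model_{eco}"))

        report = evaluate_model(model, table)
        report["selected_predictors"] = rfe_result.selected
        imp = permutation_importance(model, table,
                                     n_perm=config.n_permutations,
                                     seed=model_seed)
        ipath = out / f"importance_{eco}.csv"
        imp.to_csv(ipath, index=False)
        record(f"importance_{eco}", ipath)
        metrics_all[eco] = report

        stage(f"project:{eco}")
        surfaces = {"historical": predict_raster(model, stack, eco)}
        write_ascii_grid(surfaces["historical"].raster,
                         out / f"suitability_{eco}_historical.asc")
        record(f"suitability_{eco}_historical",
               out / f"suitability_{eco}_historical.asc")
        for label, sstack in scenario_stacks.items():
            surf = predict_raster(model, sstack, eco)
            surfaces[label] = surf
            spath = out / f"suitability_{eco}_{label}.asc"
            write_ascii_grid(surf.raster, spath)
            record(f"suitability_{eco}_{label}", spath)

        if config.scenarios:
            stage(f"shifts:{eco}")
            summaries = summarize_shifts(
                eco, surfaces, stack["elevation"], area_layer, northing,
                threshold=config.threshold,
                threshold_overrides=config.threshold_overrides,
            )
            shift_frames.append(shift_summaries_frame(summaries))

            stage(f"zonal:{eco}")
            futures = {t: s for t, s in surfaces.items() if t != "historical"}
            zdf = summarize_properties(
                surfaces["historical"], futures, props, area_layer,
                threshold=config.threshold, min_area_km2=16.7,
            )
            zonal_frames.append(zdf)

    mpath = out / "metrics.json"
    mpath.write_text(json.dumps(metrics_all, indent=2))
    record("metrics", mpath)
    if shift_frames:
        spath = out / "shift_summaries.csv"
        pd.concat(shift_frames, ignore_index=True).to_csv(spath, index=False)
        record("shift_summaries", spath)
    if zonal_frames:
        zpath = out / "zonal_summaries.csv"
        zall = pd.concat(zonal_frames, ignore_index=True)
        zall.to_csv(zpath, index=False)
        record("zonal_summaries", zpath)
        if zall["scenario"].nunique() >= 2:
            upath = out / "uncertainty_by_ownership.csv"
            multi_scenario_uncertainty(zall, "ownership").to_csv(upath, index=False)
            record("uncertainty_by_ownership", upath)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "artifacts": artifacts,
        "checksums": {k: _sha256(out / v) for k, v in artifacts.items()},
        "notes": notes,
        "wall_time_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def demo_config(out_dir: str = "ecoshift_demo", master_seed: int = 0) -> RunConfig:
    """Small two-ecosystem, two-scenario configuration that runs in
    minutes on one CPU."""
    return RunConfig(
        n_rows=60, n_cols=60,
        truths=[
            TruthModel("synthetic_montane_woodland",
                       {"bio5": -5.0, "elevation": 3.5}, intercept=-8.0),
            TruthModel("synthetic_desert_scrub",
                       {"bio5": 2.0, "bio12": -1.0}, intercept=-0.5),
        ],
        n_plots=800,
        sampling=SamplingConfig(n_pseudo=1500),
        rfe=RFEConfig(size_grid=(2, 4, 8, 12, 22), n_folds=3,
                      rank_trees=150, cv_trees=60),
        ensemble=EnsembleConfig.fast(),
        scenarios=[
            warming_scenario("SYN-GCM1", "ssp370", "2041-2060", delta_t=2.5),
            warming_scenario("SYN-GCM1", "ssp585", "2041-2060", delta_t=3.5),
        ],
        n_permutations=10,
        master_seed=master_seed,
        out_dir=out_dir,
    )


def demo(out_dir: str = "ecoshift_demo", master_seed: int = 0) -> dict:
    """Run the full synthetic pipeline at demo scale."""
    return run_experiment(demo_config(out_dir, master_seed))
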