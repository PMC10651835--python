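"""Canonical synthetic experiments used by the test-suite and examples.

These functions pin down the *study conditions* for the two headline
checks of the pipeline on a known data-generating process:

* :func:`parameter_recovery_trial` — a logistic truth driven by ``bio5``
  (negative: hot summer maxima limit the ecosystem) and ``elevation``
  (positive), calibrated to a fixed landscape prevalence; 2,000 field
  plots, the default pseudo-absence design (2,500 points, 100 km
  buffers), RFE over all 22 candidate predictors, and the stacked
  ensemble. Recovery means: held-out AUC is high, RFE retains both true
  drivers, and permutation importance ranks them on top.
* :func:`warming_shift_trial` — a uniform warming scenario applied to a
  purely temperature-limited ecosystem must move the suitable area
  upslope and north (temperature falls with elevation and northing by
  construction).

Grid scale (100 x 100 cells of 4 km) keeps a single trial at desk scale;
seeds fan out of a single integer per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box

from .evaluation import evaluate_model, permutation_importance
from .geoprep import GridSpec, northing_layer
from .sampling import (
    SamplingConfig,
    assemble_table,
    build_envelope,
    draw_pseudo_absences,
    filter_ecosystem,
)
from .sdm_ensemble import (
    EnsembleConfig,
    fit_ensemble,
    predict_raster,
    run_rfe,
    RFEConfig,
)
from .shifts import mean_position_of_suitable
from .synthgrid import (
    BioclimConfig,
    TruthModel,
    generate_bioclim,
    generate_occurrences,
    apply_scenario,
    warming_scenario,
    generate_terrain,
)

__all__ = [
    "DEFAULT_GRID",
    "default_truth",
    "build_landscape",
    "parameter_recovery_trial",
    "warming_shift_trial",
]

#: 400 km x 400 km planar landscape of 4 km cells with UTM-like northings
DEFAULT_GRID = GridSpec(
    n_rows=100, n_cols=100, cell_size=4000.0,
    origin_x=300_000.0, origin_y=4_400_000.0, crs_tag="projected",
)

TRUE_DRIVERS = ("bio5", "elevation")

#: mid-size learner settings for direction-of-shift experiments, where
#: surface smoothness matters more than squeezing out the last RMSE
SHIFT_TRIAL_ENSEMBLE = EnsembleConfig(
    n_folds=4,
    gbm_grid=(dict(n_estimators=120, max_depth=3, learning_rate=0.1),),
    xgbt_grid=(dict(n_estimators=150, max_depth=3, learning_rate=0.1),),
    xgbl_grid=(dict(n_estimators=100),),
    rf_grid=(dict(n_estimators=180),),
)


#: log-odds per SD of the experimental truth: sharply temperature-limited,
#: with an independent positive elevation effect
TRUE_COEFFS = {"bio5": -7.5, "elevation": 5.5}

#: fraction of the landscape hospitable to the synthetic ecosystem; held
#: fixed across landscape draws by calibrating the truth intercept
TRUTH_PREVALENCE = 0.10


def default_truth(stack, ecosystem_id: str = "synthetic_montane_woodland") -> TruthModel:
    """Temperature-limited montane ecosystem: suitability falls with the
    warmest-month maximum and rises with elevation, calibrated to occupy
    a fixed fraction of the given landscape."""
    return TruthModel.calibrated(ecosystem_id, TRUE_COEFFS, stack,
                                 prevalence=TRUTH_PREVALENCE)


def build_landscape(seed: int, grid: GridSpec | None = None,
                    config: BioclimConfig | None = None,
                    relief: float = 700.0):
    """Terrain + 19 bioclim layers + terrain derivatives as one stack."""
    grid = grid or DEFAULT_GRID
    ss = np.random.SeedSequence(seed)
    terrain_seed, clim_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    elevation = generate_terrain(grid, seed=terrain_seed, relief=relief)
    return generate_bioclim(elevation, config=config, seed=clim_seed)


@dataclass
class RecoveryResult:
    seed: int
    auc: float
    rmse: float
    selected: list[str]
    drivers_selected: bool
    importance_top2: list[str]
    drivers_top2: bool
    n_train: int
    n_test: int


def _build_training_table(stack, truth, n_plots, sampling, seed):
    ss = np.random.SeedSequence(seed)
    occ_seed, pa_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    occ = generate_occurrences(truth, stack, n_plots=n_plots, seed=occ_seed)
    accepted, n_cells = filter_ecosystem(occ, stack.grid, sampling)
    if not accepted:
        raise ValueError(f"only {n_cells} distinct presence cells; need "
                         f"{sampling.min_presences}")
    study_area = box(*stack.grid.extent)
    envelope = build_envelope(occ, study_area, sampling)
    pa = draw_pseudo_absences(envelope, sampling, seed=pa_seed)
    cfg = SamplingConfig(
        n_pseudo=sampling.n_pseudo,
        buffer_radius_km=sampling.buffer_radius_km,
        min_presences=sampling.min_presences,
        train_fraction=sampling.train_fraction,
        seed=seed,
    )
    return assemble_table(occ, pa, stack, cfg)


def parameter_recovery_trial(seed: int, n_plots: int = 2000,
                             grid: GridSpec | None = None,
                             sampling: SamplingConfig | None = None,
                             ensemble: EnsembleConfig | None = None,
                             rfe: RFEConfig | None = None,
                             n_perm: int = 35) -> RecoveryResult:
    """One seeded end-to-end recovery run against the known truth."""
    sampling = sampling or SamplingConfig()
    ss = np.random.SeedSequence(seed)
    land_seed, table_seed, model_seed = (
        int(s) for s in ss.generate_state(3) % (2**31)
    )
    stack = build_landscape(land_seed, grid=grid)
    truth = default_truth(stack)
    table = _build_training_table(stack, truth, n_plots, sampling, table_seed)

    rfe_result = run_rfe(table, seed=model_seed, config=rfe)
    model = fit_ensemble(table, rfe_result.selected, seed=model_seed,
                         config=ensemble)
    report = evaluate_model(model, table)
    imp = permutation_importance(model, table, n_perm=n_perm, seed=model_seed,
                                 partition="all")
    top2 = imp["predictor"].head(2).tolist()
    return RecoveryResult(
        seed=seed,
        auc=report["auc"],
        rmse=report["rmse"],
        selected=rfe_result.selected,
        drivers_selected=all(d in rfe_result.selected for d in TRUE_DRIVERS),
        importance_top2=top2,
        drivers_top2=set(top2) == set(TRUE_DRIVERS),
        n_train=len(table.train),
        n_test=len(table.test),
    )


@dataclass
class ShiftTrialResult:
    seed: int
    mean_elev_hist: float
    mean_elev_future: float
    mean_northing_hist: float
    mean_northing_future: float

    @property
    def moved_upslope(self) -> bool:
        return self.mean_elev_future > self.mean_elev_hist

    @property
    def moved_north(self) -> bool:
        return self.mean_northing_future > self.mean_northing_hist


def warming_shift_trial(seed: int, delta_t: float = 4.0,
                        n_plots: int = 2000,
                        grid: GridSpec | None = None,
                        threshold: float = 0.33,
                        ensemble: EnsembleConfig | None = None,
                        ) -> ShiftTrialResult:
    """Fit on the historical landscape, project a uniform warming, and
    measure where the suitable area moved.

    The ecosystem here is *purely* temperature-limited (logistic in bio5
    alone, calibrated to 12% prevalence) so the expected displacement
    under warming runs along both temperature gradients: upslope and
    poleward. The ensemble is fit on the full 22-predictor set (no RFE;
    subset choice is irrelevant to the direction of the shift) with a
    mid-size configuration unless one is supplied.
    """
    sampling = SamplingConfig()
    ss = np.random.SeedSequence(seed)
    land_seed, table_seed, model_seed, scen_seed = (
        int(s) for s in ss.generate_state(4) % (2**31)
    )
    # gentler relief + stronger meridional cooling: the landscape regime
    # in which a poleward displacement is detectable over random peaks
    stack = build_landscape(land_seed, grid=grid, relief=600.0,
                            config=BioclimConfig(northing_cooling=14.0))
    truth = TruthModel.calibrated("synthetic_temp_limited_scrubland",
                                  {"bio5": -6.5}, stack, prevalence=0.12)
    table = _build_training_table(stack, truth, n_plots, sampling, table_seed)
    model = fit_ensemble(table, seed=model_seed,
                         config=ensemble or SHIFT_TRIAL_ENSEMBLE)

    scenario = warming_scenario(delta_t=delta_t)
    future_stack = apply_scenario(stack, scenario, seed=scen_seed)

    hist = predict_raster(model, stack, truth.ecosystem_id)
    fut = predict_raster(model, future_stack, truth.ecosystem_id)
    dem = stack["elevation"]
    northing = northing_layer(stack.grid)
    return ShiftTrialResult(
        seed=seed,
        mean_elev_hist=mean_position_of_suitable(hist, dem, threshold),
        mean_elev_future=mean_position_of_suitable(fut, dem, threshold),
        mean_northing_hist=mean_position_of_suitable(hist, northing, threshold),
        mean_northing_future=mean_position_of_suitable(fut, northing, threshold),
    )
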