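"""Predictor optimization (RFE) and the stacked four-learner ensemble.

The suitability model is framed as *regression on 0/1 labels* optimized
for RMSE, not calibrated classification: the quantity of interest is a
continuous suitability score in [0, 1], and boosted regressors that
overshoot are clipped.

Pipeline:

* :func:`run_rfe` — random-forest importance ranking on the training
  partition, then cross-validated RMSE of a forest refit on the top-k
  predictors for each candidate subset size; the selected size minimizes
  CV RMSE (ties break toward the smaller subset).
* :func:`fit_ensemble` — four base learners (GBM, XGBT, XGBL, RF) tuned
  over small fixed grids with a shared seeded stratified K-fold, combined
  by default with RMSE-optimized non-negative blend weights fit on
  out-of-fold predictions; a gradient-boosted meta-model trained on the
  same out-of-fold predictions is the alternative "stack" combiner.
* prediction on tables (name-bound columns) and on raster stacks.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBRegressor

from .geoprep import PredictorStack
from .sampling import TrainingTable
from .shifts import SuitabilitySurface

__all__ = [
    "RFEConfig",
    "RFEResult",
    "EnsembleConfig",
    "EnsembleModel",
    "run_rfe",
    "fit_ensemble",
    "predict_table",
    "predict_raster",
]

LEARNER_TAGS = ("GBM", "XGBT", "XGBL", "RF")

DEFAULT_SIZE_GRID = (2, 4, 6, 8, 10, 12, 16, 22)


@dataclass(frozen=True)
class RFEConfig:
    """Backward feature-elimination settings.

    The ranking forest is larger than the per-size CV forests because the
    ranking is computed once while the CV loop runs |size_grid| x n_folds
    fits; both counts are desk-scale choices and configurable.
    """

    size_grid: tuple[int, ...] = DEFAULT_SIZE_GRID
    n_folds: int = 4
    rank_trees: int = 250
    rank_permutations: int = 5
    cv_trees: int = 50


@dataclass
class RFEResult:
    ranking: list[str]              # all predictors, most important first
    rmse_by_size: dict[int, float]  # subset size -> CV RMSE
    selected: list[str]             # top-k at the RMSE minimum

    @property
    def selected_size(self) -> int:
        return len(self.selected)


def run_rfe(table: TrainingTable, size_grid: Sequence[int] | None = None,
            seed: int = 0, config: RFEConfig | None = None) -> RFEResult:
    """Rank predictors by forest importance and pick the CV-RMSE-optimal
    subset size.

    Sizes exceeding the number of predictors are truncated with a warning;
    ties in CV RMSE resolve to the smaller subset.
    """
    cfg = config or RFEConfig()
    sizes = tuple(size_grid) if size_grid is not None else cfg.size_grid
    predictors = table.predictors
    if len(predictors) < 1:
        raise ValueError("table has no predictors")
    train = table.train
    y = train["label"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("train partition needs both labels")
    X = train[predictors].to_numpy(dtype=float)

    usable = sorted({min(s, len(predictors)) for s in sizes if s >= 1})
    if max(sizes) > len(predictors):
        warnings.warn("size_grid truncated to the number of predictors")

    # permutation importance of a single forest gives the ranking, as RF
    # regression importance is conventionally permutation-based
    from sklearn.inspection import permutation_importance as _sk_perm

    rank_rf = RandomForestRegressor(
        n_estimators=cfg.rank_trees, random_state=seed, n_jobs=1
    ).fit(X, y)
    perm = _sk_perm(rank_rf, X, y, n_repeats=cfg.rank_permutations,
                    random_state=seed, n_jobs=1)
    order = np.argsort(perm.importances_mean)[::-1]
    ranking = [predictors[i] for i in order]

    if len(predictors) == 1:
        return RFEResult(ranking, {1: float("nan")}, ranking[:1])

    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y.astype(int)))
    rmse_by_size: dict[int, float] = {}
    for k in usable:
        cols = [predictors.index(name) for name in ranking[:k]]
        Xk = X[:, cols]
        sq = 0.0
        for tr, te in folds:
            rf = RandomForestRegressor(
                n_estimators=cfg.cv_trees, random_state=seed, n_jobs=1
            ).fit(Xk[tr], y[tr])
            resid = rf.predict(Xk[te]) - y[te]
            sq += float(resid @ resid)
        rmse_by_size[k] = float(np.sqrt(sq / len(y)))
    best = min(usable, key=lambda k: (rmse_by_size[k], k))
    return RFEResult(ranking, rmse_by_size, ranking[:best])


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameter grids and CV design for the four base learners.

    Each grid is a tuple of keyword dicts tried by shared-fold CV; the
    defaults are single, modest settings chosen for desk-scale runtimes.
    :meth:`tuned` returns the wider search grid (trees 250/500, depth 2/3,
    learning rate 0.05/0.1) for runs where the extra tuning is worth the
    wall time.
    """

    n_folds: int = 10
    gbm_grid: tuple = (dict(n_estimators=160, max_depth=3, learning_rate=0.1),)
    xgbt_grid: tuple = (dict(n_estimators=250, max_depth=3, learning_rate=0.1),)
    xgbl_grid: tuple = (dict(n_estimators=200),)
    rf_grid: tuple = (dict(n_estimators=280),)
    #: "weights" blends base predictions with RMSE-optimized non-negative
    #: weights; "stack" uses the gradient-boosted meta-model instead
    combiner: str = "weights"
    meta_params: Mapping[str, object] = field(
        default_factory=lambda: dict(n_estimators=100, max_depth=2,
                                     learning_rate=0.1)
    )

    @classmethod
    def tuned(cls) -> "EnsembleConfig":
        boosted = tuple(
            dict(n_estimators=n, max_depth=d, learning_rate=lr)
            for n in (250, 500) for d in (2, 3) for lr in (0.05, 0.1)
        )
        return cls(gbm_grid=boosted, xgbt_grid=boosted,
                   xgbl_grid=(dict(n_estimators=200), dict(n_estimators=500)),
                   rf_grid=(dict(n_estimators=500),))

    @classmethod
    def fast(cls) -> "EnsembleConfig":
        """Reduced folds/trees for quick experiments and smoke tests."""
        return cls(
            n_folds=5,
            gbm_grid=(dict(n_estimators=120, max_depth=3, learning_rate=0.1),),
            xgbt_grid=(dict(n_estimators=150, max_depth=3, learning_rate=0.1),),
            xgbl_grid=(dict(n_estimators=100),),
            rf_grid=(dict(n_estimators=150),),
        )


def _make_learner(tag: str, params: Mapping[str, object], seed: int):
    if tag == "GBM":
        return GradientBoostingRegressor(random_state=seed, **params)
    if tag == "XGBT":
        return XGBRegressor(tree_method="hist", n_jobs=1, random_state=seed,
                            verbosity=0, **params)
    if tag == "XGBL":
        return XGBRegressor(booster="gblinear", n_jobs=1, random_state=seed,
                            verbosity=0, **params)
    if tag == "RF":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown learner tag {tag!r}")


@dataclass
class EnsembleModel:
    """Fitted stacked ensemble.

    ``base_learners`` maps tag -> fitted regressor (refit on the full
    training partition with its CV-best parameters). The default combiner
    averages base predictions with inverse CV-RMSE ``weights``; when
    ``combiner`` is "stack", the gradient-boosted ``meta`` (trained on
    out-of-fold base predictions only) is used instead, falling back to
    the weights if the meta fit was degenerate. Predictions are always
    clipped to [0, 1].
    """

    predictors: list[str]
    base_learners: dict
    meta: object | None
    weights: dict[str, float]
    cv_rmse: dict[str, float]
    best_params: dict[str, dict]
    seed: int
    combiner: str = "weights"

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return predict_table(self, rows)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        base = np.column_stack(
            [self.base_learners[tag].predict(X) for tag in LEARNER_TAGS]
        )
        if self.combiner == "stack" and self.meta is not None:
            pred = self.meta.predict(base)
        else:
            w = np.array([self.weights[tag] for tag in LEARNER_TAGS])
            pred = base @ w
        return np.clip(pred, 0.0, 1.0)

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for tag, learner in self.base_learners.items():
            with (directory / f"{tag}.pkl").open("wb") as fh:
                pickle.dump(learner, fh)
        with (directory / "meta.pkl").open("wb") as fh:
            pickle.dump(self.meta, fh)
        manifest = {
            "predictors": self.predictors,
            "weights": self.weights,
            "cv_rmse": self.cv_rmse,
            "best_params": self.best_params,
            "seed": self.seed,
            "combiner": self.combiner,
        }
        mpath = directory / "model.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        return mpath

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        manifest = json.loads((directory / "model.json").read_text())
        learners = {}
        for tag in LEARNER_TAGS:
            with (directory / f"{tag}.pkl").open("rb") as fh:
                learners[tag] = pickle.load(fh)
        with (directory / "meta.pkl").open("rb") as fh:
            meta = pickle.load(fh)
        return cls(
            predictors=manifest["predictors"],
            base_learners=learners,
            meta=meta,
            weights=manifest["weights"],
            cv_rmse=manifest["cv_rmse"],
            best_params=manifest["best_params"],
            seed=manifest["seed"],
            combiner=manifest.get("combiner", "weights"),
        )


def fit_ensemble(table: TrainingTable, predictors: Sequence[str] | None = None,
                 seed: int = 0,
                 config: EnsembleConfig | None = None) -> EnsembleModel:
    """Fit the four base learners + meta combiner on the train partition.

    One seeded stratified fold assignment is shared by every learner and
    grid point, so CV comparisons are paired. The meta-model only ever
    sees out-of-fold base predictions, never resubstitution fits.
    """
    cfg = config or EnsembleConfig()
    predictors = list(predictors) if predictors is not None else table.predictors
    missing = [p for p in predictors if p not in table.df.columns]
    if missing:
        raise ValueError(f"predictors not in table: {missing}")
    if not predictors:
        raise ValueError("need at least one predictor")
    train = table.train
    y = train["label"].to_numpy(dtype=float)
    X = train[predictors].to_numpy(dtype=float)
    classes = np.unique(y)

    grids = {
        "GBM": cfg.gbm_grid, "XGBT": cfg.xgbt_grid,
        "XGBL": cfg.xgbl_grid, "RF": cfg.rf_grid,
    }

    if len(classes) < 2:
        # constant-label degenerate fit: every learner memorizes the constant
        learners = {}
        best_params = {}
        for tag, grid in grids.items():
            learners[tag] = _make_learner(tag, grid[0], seed).fit(X, y)
            best_params[tag] = dict(grid[0])
        weights = {tag: 0.25 for tag in LEARNER_TAGS}
        return EnsembleModel(predictors, learners, None, weights,
                             {tag: 0.0 for tag in LEARNER_TAGS},
                             best_params, seed, cfg.combiner)

    n_folds = min(cfg.n_folds, int(min(np.bincount(y.astype(int))))) or 2
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y.astype(int)))

    oof_best: dict[str, np.ndarray] = {}
    cv_rmse: dict[str, float] = {}
    best_params: dict[str, dict] = {}
    for tag, grid in grids.items():
        best = None
        for params in grid:
            oof = np.empty_like(y)
            for tr, te in folds:
                learner = _make_learner(tag, params, seed)
                learner.fit(X[tr], y[tr])
                oof[te] = learner.predict(X[te])
            rmse = float(np.sqrt(np.mean((oof - y) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, dict(params), oof)
        cv_rmse[tag], best_params[tag], oof_best[tag] = best

    # RMSE-based blend weights: non-negative least squares on the
    # out-of-fold prediction matrix (the optimized blend); degenerate
    # solutions fall back to inverse-RMSE weighting
    meta_X = np.column_stack([oof_best[tag] for tag in LEARNER_TAGS])
    from scipy.optimize import nnls as _nnls

    w_opt, _ = _nnls(meta_X, y)
    if not np.any(w_opt > 0):
        inv = np.array([1.0 / max(cv_rmse[tag], 1e-9) for tag in LEARNER_TAGS])
        w_opt = inv / inv.sum()
    weights = dict(zip(LEARNER_TAGS, w_opt.tolist()))

    meta: object | None
    if np.allclose(meta_X.std(axis=0), 0.0):
        meta = None  # degenerate base predictions; fall back to weights
    else:
        meta = GradientBoostingRegressor(random_state=seed, **cfg.meta_params)
        meta.fit(meta_X, y)

    learners = {
        tag: _make_learner(tag, best_params[tag], seed).fit(X, y)
        for tag in LEARNER_TAGS
    }
    return EnsembleModel(predictors, learners, meta, weights, cv_rmse,
                         best_params, seed, cfg.combiner)


def predict_table(model: EnsembleModel, rows: pd.DataFrame) -> np.ndarray:
    """Suitability in [0, 1] for each row; columns are bound by name."""
    missing = [p for p in model.predictors if p not in rows.columns]
    if missing:
        raise ValueError(f"missing predictor column(s): {missing}")
    X = rows[model.predictors].to_numpy(dtype=float)
    return model.predict_matrix(X)


def predict_raster(model: EnsembleModel, stack: PredictorStack,
                   ecosystem_id: str = "") -> SuitabilitySurface:
    """Per-cell suitability surface on the stack's grid.

    Masked cells stay masked; the surface inherits the stack's period tag.
    """
    from .geoprep import RasterLayer

    missing = [p for p in model.predictors if p not in stack]
    if missing:
        raise ValueError(f"stack lacks predictor layer(s): {missing}")
    mask = stack.combined_mask
    rows, cols = np.nonzero(~mask)
    vals = np.zeros(stack.grid.shape, dtype=float)
    if len(rows):
        X = stack.values_at(rows, cols, model.predictors)
        vals[rows, cols] = model.predict_matrix(X)
    layer = RasterLayer("suitability", stack.grid, vals, mask)
    return SuitabilitySurface(ecosystem_id=ecosystem_id,
                              period_tag=stack.period_tag, raster=layer)
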