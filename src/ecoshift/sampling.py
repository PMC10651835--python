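"""Training-table construction: envelopes, pseudo-absences, dedup, split.

Presence-only occurrence records are turned into a labelled table by

1. screening the ecosystem for a minimum number of distinct-cell records,
2. buffering every record by a fixed radius and unioning the disks into a
   "polygon envelope" clipped to the study area,
3. dropping a fixed number of uniform pseudo-absence points inside the
   envelope (label 0) — no climatic rejection and no exclusion zone
   around presences, so absences may land within one grid cell of them,
4. deduplicating to one row per grid cell with presence priority, joining
   predictor values at cell centers, and
5. a seeded, label-stratified train/test split.

Pseudo-absence counts are deliberately NOT rebalanced to match presence
counts; the class imbalance is part of the design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point
from shapely import unary_union

from .geoprep import GridSpec, PredictorStack

__all__ = [
    "SamplingConfig",
    "TrainingTable",
    "filter_ecosystem",
    "build_envelope",
    "draw_pseudo_absences",
    "assemble_table",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Pseudo-absence design. Radii are kilometres; coordinates metres."""

    n_pseudo: int = 2500
    buffer_radius_km: float = 100.0
    min_presences: int = 50
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.buffer_radius_km <= 0:
            raise ValueError("buffer_radius_km must be positive")


@dataclass
class TrainingTable:
    """Labelled, deduplicated model rows plus their provenance.

    ``df`` columns: ``cell_row, cell_col, plot_id, label, partition`` and
    one column per predictor. Exactly one row per grid cell; ``label`` is
    1 for presence, 0 for pseudo-absence; ``partition`` is "train" or
    "test".
    """

    df: pd.DataFrame
    predictors: list[str]
    grid: GridSpec
    config: SamplingConfig

    @property
    def train(self) -> pd.DataFrame:
        return self.df[self.df["partition"] == "train"]

    @property
    def test(self) -> pd.DataFrame:
        return self.df[self.df["partition"] == "test"]

    def save(self, path: str | Path) -> None:
        """CSV with a commented JSON header carrying grid + config."""
        path = Path(path)
        meta = {
            "grid": asdict(self.grid),
            "config": asdict(self.config),
            "predictors": self.predictors,
        }
        with path.open("w") as fh:
            fh.write("# ecoshift-training-table " + json.dumps(meta) + "\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TrainingTable":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline()
            if not header.startswith("# ecoshift-training-table "):
                raise ValueError("not a training-table file")
            meta = json.loads(header[len("# ecoshift-training-table "):])
            df = pd.read_csv(fh)
        return cls(
            df=df,
            predictors=list(meta["predictors"]),
            grid=GridSpec(**meta["grid"]),
            config=SamplingConfig(**meta["config"]),
        )


def filter_ecosystem(records: pd.DataFrame, grid: GridSpec,
                     config: SamplingConfig | None = None):
    """Minimum-sample screen on *distinct grid cells* with a presence.

    Returns ``(accepted, distinct_cell_count)``. Plots piling into the
    same cell count once, so 120 records in 40 cells fail a 50-cell
    minimum.
    """
    config = config or SamplingConfig()
    if len(records) == 0:
        return False, 0
    if records["ecosystem_id"].nunique() > 1:
        raise ValueError("records must all share one ecosystem_id")
    rows, cols = grid.cell_of(records["x"].to_numpy(), records["y"].to_numpy())
    count = len(set(zip(rows.tolist(), cols.tolist())))
    return count >= config.min_presences, count


def build_envelope(records: pd.DataFrame, study_area,
                   config: SamplingConfig | None = None):
    """Union of buffer disks around records, clipped to the study area."""
    config = config or SamplingConfig()
    if len(records) == 0:
        raise ValueError("cannot build an envelope from zero records")
    radius_m = config.buffer_radius_km * 1000.0
    disks = MultiPoint(
        [Point(x, y) for x, y in zip(records["x"], records["y"])]
    ).buffer(radius_m)
    envelope = disks.intersection(study_area)
    if envelope.is_empty:
        raise ValueError("envelope does not intersect the study area")
    return envelope


def convex_hull_envelope(records: pd.DataFrame, study_area):
    """Alternative envelope for sensitivity checks: convex hull of records."""
    hull = MultiPoint(
        [Point(x, y) for x, y in zip(records["x"], records["y"])]
    ).convex_hull
    envelope = hull.intersection(study_area)
    if envelope.is_empty:
        raise ValueError("envelope does not intersect the study area")
    return envelope


def draw_pseudo_absences(envelope, config: SamplingConfig | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Uniform points inside the envelope via seeded rejection sampling."""
    import shapely

    config = config or SamplingConfig()
    if envelope.is_empty or envelope.area <= 0:
        raise ValueError("envelope is degenerate; cannot place points")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    xmin, ymin, xmax, ymax = envelope.bounds
    n = config.n_pseudo
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    got = 0
    # acceptance rate = envelope area / bbox area; guard against degenerate
    # slivers that would loop forever
    rate = envelope.area / ((xmax - xmin) * (ymax - ymin))
    if rate < 1e-6:
        raise ValueError("envelope too thin for rejection sampling")
    while got < n:
        m = max(int((n - got) / max(rate, 0.05)) + 32, 64)
        cx = rng.uniform(xmin, xmax, m)
        cy = rng.uniform(ymin, ymax, m)
        inside = shapely.contains_xy(envelope, cx, cy)
        xs.append(cx[inside])
        ys.append(cy[inside])
        got += int(inside.sum())
    x = np.concatenate(xs)[:n]
    y = np.concatenate(ys)[:n]
    return pd.DataFrame({"x": x, "y": y})


def _stratified_split(labels: np.ndarray, train_fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Boolean train indicator with round(frac * n) train rows per label."""
    is_train = np.zeros(len(labels), dtype=bool)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n_train = int(round(train_fraction * len(idx)))
        chosen = rng.permutation(idx)[:n_train]
        is_train[chosen] = True
    return is_train


def assemble_table(presences: pd.DataFrame, pseudo_absences: pd.DataFrame,
                   stack: PredictorStack,
                   config: SamplingConfig | None = None) -> TrainingTable:
    """Combine, deduplicate, intersect with predictors, and split.

    Per-cell dedup keeps one row per grid cell: any presence in the cell
    supersedes all absences there; within a label, the lowest ``plot_id``
    wins (pseudo-absences get synthetic ids after the presences). Rows on
    cells masked in any predictor layer are dropped, and the result gets a
    seeded stratified 80/20 split.
    """
    config = config or SamplingConfig()
    grid = stack.grid

    pres = presences.copy()
    pres["label"] = 1
    if "plot_id" not in pres:
        pres["plot_id"] = np.arange(len(pres))
    pa = pseudo_absences.copy()
    pa["label"] = 0
    pa["plot_id"] = int(pres["plot_id"].max() if len(pres) else 0) + 1 + np.arange(len(pa))
    both = pd.concat(
        [pres[["plot_id", "x", "y", "label"]], pa[["plot_id", "x", "y", "label"]]],
        ignore_index=True,
    )
    rows, cols = grid.cell_of(both["x"].to_numpy(), both["y"].to_numpy())
    both["cell_row"] = rows
    both["cell_col"] = cols
    inside = (
        (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    )
    both = both[inside]

    # presence priority, then lowest plot_id; sort gives deterministic dedup
    both = both.sort_values(
        ["cell_row", "cell_col", "label", "plot_id"],
        ascending=[True, True, False, True],
    )
    both = both.drop_duplicates(["cell_row", "cell_col"], keep="first")

    ok = ~stack.combined_mask
    both = both[ok[both["cell_row"].to_numpy(), both["cell_col"].to_numpy()]]
    both = both.reset_index(drop=True)

    if (both["label"] == 1).sum() == 0 or (both["label"] == 0).sum() == 0:
        raise ValueError("need at least one presence and one pseudo-absence cell")

    predictors = stack.names
    X = stack.values_at(both["cell_row"].to_numpy(), both["cell_col"].to_numpy(),
                        predictors)
    for j, name in enumerate(predictors):
        both[name] = X[:, j]

    rng = np.random.default_rng(config.seed)
    is_train = _stratified_split(both["label"].to_numpy(), config.train_fraction, rng)
    both["partition"] = np.where(is_train, "train", "test")
    cols_order = ["cell_row", "cell_col", "plot_id", "label", "partition"] + predictors
    return TrainingTable(both[cols_order], predictors, grid, config)
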