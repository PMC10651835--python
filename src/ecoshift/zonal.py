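"""Zonal suitability summaries inside property polygons.

Cell contributions are apportioned by the *fraction of each cell's area
inside the polygon* (default), so properties smaller than one cell are
still summarized honestly; a faster cell-center membership mode is
available. Cross-scenario uncertainty statistics aggregate per-property
percent differences by state, ownership class or managing agency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape

from .geoprep import RasterLayer
from .shifts import (
    DEFAULT_SUITABILITY_THRESHOLD,
    SuitabilitySurface,
    percent_difference,
)
from .synthgrid import PropertyPolygon

__all__ = [
    "zonal_area",
    "summarize_properties",
    "multi_scenario_uncertainty",
    "write_properties_geojson",
    "read_properties_geojson",
]


def _cell_fractions(polygon, grid, method: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rows, cols, fraction-inside) for cells touching the polygon."""
    xmin, ymin, xmax, ymax = polygon.bounds
    r0, c0 = grid.cell_of(xmin, ymax)
    r1, c1 = grid.cell_of(xmax, ymin)
    r0 = max(int(r0), 0)
    c0 = max(int(c0), 0)
    r1 = min(int(r1), grid.n_rows - 1)
    c1 = min(int(c1), grid.n_cols - 1)
    if r1 < r0 or c1 < c0:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    rows, cols, fracs = [], [], []
    cs = grid.cell_size
    if method == "center":
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                             indexing="ij")
        rr = rr.ravel()
        cc = cc.ravel()
        cx = grid.origin_x + (cc + 0.5) * cs
        cy = grid.origin_y - (rr + 0.5) * cs
        inside = shapely.contains_xy(polygon, cx, cy)
        return rr[inside], cc[inside], np.ones(int(inside.sum()))
    prepared = shapely.prepared.prep(polygon)
    for r in range(r0, r1 + 1):
        top = grid.origin_y - r * cs
        for c in range(c0, c1 + 1):
            left = grid.origin_x + c * cs
            cell = box(left, top - cs, left + cs, top)
            if prepared.contains(cell):
                f = 1.0
            elif prepared.intersects(cell):
                f = cell.intersection(polygon).area / cell.area
            else:
                continue
            if f > 0:
                rows.append(r)
                cols.append(c)
                fracs.append(f)
    return np.asarray(rows, int), np.asarray(cols, int), np.asarray(fracs)


def zonal_area(surface: SuitabilitySurface,
               polygons: Sequence[PropertyPolygon],
               area_layer: RasterLayer,
               threshold: float = DEFAULT_SUITABILITY_THRESHOLD,
               method: str = "fractional") -> pd.DataFrame:
    """Per-property suitability-weighted area (km²).

    Each passing cell contributes ``s * A * f`` where ``f`` is the
    fraction of the cell inside the polygon (or 1 under the cell-center
    rule). Returns columns ``property_id, area_km2, n_cells``.
    """
    if method not in ("fractional", "center"):
        raise ValueError(f"unknown method {method!r}")
    grid = surface.raster.grid
    if area_layer.grid != grid:
        raise ValueError("surface and area layer are on different grids")
    s = surface.raster.values
    ok = ~(surface.raster.mask | area_layer.mask)
    passing = ok & (s >= threshold)
    records = []
    for prop in polygons:
        geom = prop.geometry
        if geom.is_empty or not geom.is_valid:
            raise ValueError(f"invalid geometry for property {prop.property_id}")
        rows, cols, fracs = _cell_fractions(geom, grid, method)
        if len(rows):
            keep = passing[rows, cols]
            rows, cols, fracs = rows[keep], cols[keep], fracs[keep]
        total = float(np.sum(s[rows, cols] * area_layer.values[rows, cols] * fracs)) \
            if len(rows) else 0.0
        records.append({
            "property_id": prop.property_id,
            "area_km2": total,
            "n_cells": int(len(rows)),
        })
    return pd.DataFrame(records)


def summarize_properties(hist_surface: SuitabilitySurface,
                         future_surfaces: Mapping[str, SuitabilitySurface],
                         polygons: Sequence[PropertyPolygon],
                         area_layer: RasterLayer,
                         threshold: float = DEFAULT_SUITABILITY_THRESHOLD,
                         method: str = "fractional",
                         min_area_km2: float | None = None) -> pd.DataFrame:
    """Per property x scenario change summary with the ±50% flag.

    ``flag_ge50`` is True when |pct_diff| >= 50. Properties with no
    historical suitable overlap get null percent fields and are excluded
    from the property rollup (``rollup_ge50`` on any row of the property).
    ``min_area_km2`` tags properties whose polygon area falls below a
    reporting cut (``below_min_area``) without excluding them.
    """
    hist = zonal_area(hist_surface, polygons, area_layer, threshold, method)
    hist = hist.rename(columns={"area_km2": "area_hist"})[["property_id", "area_hist"]]
    attrs = pd.DataFrame([
        {
            "property_id": p.property_id,
            "name": p.name,
            "state": p.state,
            "ownership": p.ownership,
            "agency": p.agency,
            "polygon_km2": p.geometry.area / 1e6,
        }
        for p in polygons
    ])
    frames = []
    for scenario, surf in future_surfaces.items():
        fut = zonal_area(surf, polygons, area_layer, threshold, method)
        fut = fut.rename(columns={"area_km2": "area_future"})[["property_id", "area_future"]]
        df = hist.merge(fut, on="property_id")
        df["ecosystem_id"] = hist_surface.ecosystem_id
        df["scenario"] = scenario
        df["pct_diff"] = [
            percent_difference(h, f) if h > 0 else np.nan
            for h, f in zip(df["area_hist"], df["area_future"])
        ]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True).merge(attrs, on="property_id")
    out["flag_ge50"] = out["pct_diff"].abs() >= 50.0
    out.loc[out["pct_diff"].isna(), "flag_ge50"] = False
    if min_area_km2 is not None:
        out["below_min_area"] = out["polygon_km2"] < min_area_km2
    rollup = out.groupby("property_id")["flag_ge50"].any().rename("rollup_ge50")
    return out.merge(rollup, on="property_id")


def multi_scenario_uncertainty(summaries: pd.DataFrame,
                               group_by: str = "ownership",
                               value: str = "pct_diff") -> pd.DataFrame:
    """Across-scenario spread of percent change per zone.

    ``summaries`` needs a ``scenario`` column plus the grouping column;
    statistics (mean, SD, min, quartiles, max) are computed over the
    per-scenario zone totals. At least two scenarios are required.
    """
    if summaries["scenario"].nunique() < 2:
        raise ValueError("uncertainty needs at least two scenarios")
    per_zone_scenario = (
        summaries.dropna(subset=[value])
        .groupby([group_by, "scenario"])[value]
        .mean()
        .reset_index()
    )

    def stats(g: pd.Series) -> pd.Series:
        return pd.Series({
            "n_scenarios": g.size,
            "mean": g.mean(),
            "sd": g.std(ddof=1),
            "min": g.min(),
            "q1": g.quantile(0.25),
            "median": g.median(),
            "q3": g.quantile(0.75),
            "max": g.max(),
        })

    return (
        per_zone_scenario.groupby(group_by)[value]
        .apply(stats)
        .unstack()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# GeoJSON round-trip
# ---------------------------------------------------------------------------

def write_properties_geojson(polygons: Iterable[PropertyPolygon],
                             path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "property_id": p.property_id,
                "name": p.name,
                "state": p.state,
                "ownership": p.ownership,
                "agency": p.agency,
            },
            "geometry": mapping(p.geometry),
        }
        for p in polygons
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_properties_geojson(path: str | Path) -> list[PropertyPolygon]:
    data = json.loads(Path(path).read_text())
    return [
        PropertyPolygon(
            property_id=f["properties"]["property_id"],
            name=f["properties"].get("name", ""),
            state=f["properties"].get("state", ""),
            ownership=f["properties"].get("ownership", "PVT"),
            agency=f["properties"].get("agency", "none"),
            geometry=shape(f["geometry"]),
        )
        for f in data["features"]
    ]
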