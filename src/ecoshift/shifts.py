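"""Quantifying suitability change: area, elevation, northing, transitions.

Area totals are suitability-weighted: every cell at or above the
suitability cutoff contributes ``s * A_cell`` (cutoff default 0.33,
overridable per ecosystem; a 0.5 preset matches high-suitability
bookkeeping). Elevation and northing shifts are *unweighted* means of the
position layer over the cells passing the cutoff. Transition classes
follow fixed historical-vs-future suitability bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .geoprep import RasterLayer

__all__ = [
    "SuitabilitySurface",
    "ShiftSummary",
    "TransitionRaster",
    "TRANSITION_CODES",
    "suitability_area",
    "percent_difference",
    "mean_position_of_suitable",
    "classify_transitions",
    "summarize_shifts",
    "DEFAULT_SUITABILITY_THRESHOLD",
    "HIGH_SUITABILITY_THRESHOLD",
]

DEFAULT_SUITABILITY_THRESHOLD = 0.33
#: cutoff used for "high suitability" area bookkeeping and zonal rollups
HIGH_SUITABILITY_THRESHOLD = 0.5

TRANSITION_CODES = {
    "unchanged": 0,
    "high_increase": 1,
    "moderate_increase": 2,
    "large_loss": 3,
    "moderate_loss": 4,
}


@dataclass
class SuitabilitySurface:
    """Per-ecosystem, per-period suitability raster with values in [0, 1]."""

    ecosystem_id: str
    period_tag: str
    raster: RasterLayer

    def __post_init__(self) -> None:
        vals = self.raster.values[~self.raster.mask]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")


@dataclass
class ShiftSummary:
    """Area/elevation/northing change for one ecosystem x scenario."""

    ecosystem_id: str
    scenario: str
    threshold_used: float
    area_hist: float
    area_future: float
    pct_area_diff: float
    area_hist_unweighted: float
    area_future_unweighted: float
    mean_elev_hist: float
    mean_elev_future: float
    pct_elev_diff: float
    mean_northing_hist: float
    mean_northing_future: float
    pct_northing_diff: float


@dataclass
class TransitionRaster:
    """Per-cell transition class (see TRANSITION_CODES) with provenance."""

    classes: np.ndarray
    mask: np.ndarray
    provenance: tuple[str, str]

    def counts(self) -> dict[str, int]:
        ok = ~self.mask
        return {
            name: int(np.sum(self.classes[ok] == code))
            for name, code in TRANSITION_CODES.items()
        }


def _check_same_grid(a: RasterLayer, b: RasterLayer) -> None:
    if a.grid != b.grid:
        raise ValueError("layers are not on the same grid")


def suitability_area(surface: SuitabilitySurface, area_layer: RasterLayer,
                     threshold: float = DEFAULT_SUITABILITY_THRESHOLD) -> float:
    """Suitability-weighted area (km²): sum of s*A over cells with
    s >= threshold."""
    _check_same_grid(surface.raster, area_layer)
    s = surface.raster.values
    ok = ~(surface.raster.mask | area_layer.mask) & (s >= threshold)
    return float(np.sum(s[ok] * area_layer.values[ok]))


def suitable_cell_area(surface: SuitabilitySurface, area_layer: RasterLayer,
                       threshold: float = DEFAULT_SUITABILITY_THRESHOLD) -> float:
    """Unweighted variant: total cell area (km²) passing the cutoff."""
    _check_same_grid(surface.raster, area_layer)
    s = surface.raster.values
    ok = ~(surface.raster.mask | area_layer.mask) & (s >= threshold)
    return float(np.sum(area_layer.values[ok]))


def percent_difference(hist: float, future: float) -> float:
    """100 * (future - hist) / hist; undefined (error) for hist <= 0."""
    if hist <= 0:
        raise ValueError("percent difference undefined for a zero baseline")
    return 100.0 * (future - hist) / hist


def mean_position_of_suitable(surface: SuitabilitySurface,
                              position_layer: RasterLayer,
                              threshold: float = DEFAULT_SUITABILITY_THRESHOLD,
                              ) -> float:
    """Unweighted mean of a position layer (elevation or northing) over
    cells with suitability >= threshold."""
    _check_same_grid(surface.raster, position_layer)
    s = surface.raster.values
    ok = ~(surface.raster.mask | position_layer.mask) & (s >= threshold)
    if not ok.any():
        raise ValueError("no cell passes the suitability threshold")
    return float(position_layer.values[ok].mean())


def classify_transitions(hist: SuitabilitySurface,
                         future: SuitabilitySurface) -> TransitionRaster:
    """Classify each cell by historical-vs-future suitability bands.

    high_increase:     future >= 0.5  and hist < 0.5
    large_loss:        future <  0.5  and hist >= 0.5
    moderate_increase: 0.25 <= future < 0.5 and hist < 0.25
    moderate_loss:     future < 0.25 and 0.25 <= hist < 0.5
    unchanged:         everything else
    """
    _check_same_grid(hist.raster, future.raster)
    h = hist.raster.values
    f = future.raster.values
    mask = hist.raster.mask | future.raster.mask
    cls = np.full(h.shape, TRANSITION_CODES["unchanged"], dtype=int)
    rules = [
        ("high_increase", (f >= 0.5) & (h < 0.5)),
        ("large_loss", (f < 0.5) & (h >= 0.5)),
        ("moderate_increase", (f >= 0.25) & (f < 0.5) & (h < 0.25)),
        ("moderate_loss", (f < 0.25) & (h >= 0.25) & (h < 0.5)),
    ]
    assigned = np.zeros(h.shape, dtype=bool)
    for name, hit in rules:
        hit = hit & ~assigned
        cls[hit] = TRANSITION_CODES[name]
        assigned |= hit
    cls[mask] = TRANSITION_CODES["unchanged"]
    return TransitionRaster(cls, mask, (hist.period_tag, future.period_tag))


def summarize_shifts(ecosystem_id: str,
                     surfaces: Mapping[str, SuitabilitySurface],
                     dem: RasterLayer,
                     area_layer: RasterLayer,
                     northing: RasterLayer,
                     threshold: float = DEFAULT_SUITABILITY_THRESHOLD,
                     threshold_overrides: Mapping[str, float] | None = None,
                     ) -> list[ShiftSummary]:
    """One ShiftSummary per non-historical surface.

    ``surfaces`` maps period tags to surfaces and must contain
    "historical". ``threshold_overrides`` maps ecosystem ids to their
    cutoff (the per-ecosystem exception mechanism).
    """
    if "historical" not in surfaces:
        raise ValueError("surfaces must include a 'historical' entry")
    thr = (threshold_overrides or {}).get(ecosystem_id, threshold)
    hist = surfaces["historical"]
    area_h = suitability_area(hist, area_layer, thr)
    area_h_u = suitable_cell_area(hist, area_layer, thr)
    elev_h = mean_position_of_suitable(hist, dem, thr)
    north_h = mean_position_of_suitable(hist, northing, thr)
    out = []
    for tag, surf in surfaces.items():
        if tag == "historical":
            continue
        area_f = suitability_area(surf, area_layer, thr)
        area_f_u = suitable_cell_area(surf, area_layer, thr)
        elev_f = mean_position_of_suitable(surf, dem, thr)
        north_f = mean_position_of_suitable(surf, northing, thr)
        out.append(ShiftSummary(
            ecosystem_id=ecosystem_id,
            scenario=tag,
            threshold_used=thr,
            area_hist=area_h,
            area_future=area_f,
            pct_area_diff=percent_difference(area_h, area_f),
            area_hist_unweighted=area_h_u,
            area_future_unweighted=area_f_u,
            mean_elev_hist=elev_h,
            mean_elev_future=elev_f,
            pct_elev_diff=percent_difference(elev_h, elev_f),
            mean_northing_hist=north_h,
            mean_northing_future=north_f,
            pct_northing_diff=percent_difference(north_h, north_f),
        ))
    return out


def shift_summaries_frame(summaries: list[ShiftSummary]) -> pd.DataFrame:
    """Tidy one-row-per-metric DataFrame for CSV export."""
    rows = []
    for s in summaries:
        for metric in (
            "area_hist", "area_future", "pct_area_diff",
            "area_hist_unweighted", "area_future_unweighted",
            "mean_elev_hist", "mean_elev_future", "pct_elev_diff",
            "mean_northing_hist", "mean_northing_future", "pct_northing_diff",
        ):
            rows.append({
                "ecosystem_id": s.ecosystem_id,
                "scenario": s.scenario,
                "threshold": s.threshold_used,
                "metric": metric,
                "value": getattr(s, metric),
            })
    return pd.DataFrame(rows)
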