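"""Grid data model, terrain derivatives, resampling and pixel areas.

The analysis operates on rectangular grids of square cells. A grid is
described by a :class:`GridSpec`; a single named variable on a grid is a
:class:`RasterLayer`; an ordered set of layers sharing one grid is a
:class:`PredictorStack`. Two conventions are used throughout:

* row 0 is the northernmost row, and ``origin_x/origin_y`` locate the
  *upper-left corner* of the upper-left cell;
* cell membership of a point is decided by flooring its offset from the
  origin, so cells tile the plane without overlap, and all stages use
  cell centers (``origin + (index + 0.5) * cell_size``) when they need a
  representative point for a cell.

Projected grids carry coordinates in metres (``crs_tag`` != "geographic");
geographic grids carry degrees and are used for latitude-dependent pixel
areas.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "GridSpec",
    "RasterLayer",
    "PredictorStack",
    "compute_slope",
    "compute_aspect",
    "compute_trasp",
    "resample_nearest",
    "pixel_area",
    "northing_layer",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_stack",
    "read_stack",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular grid of square cells.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    cell_size
        Cell edge length, degrees for geographic grids and metres for
        projected grids. Must be positive.
    origin_x, origin_y
        Coordinate of the upper-left corner of cell (0, 0).
    crs_tag
        "geographic" for degree grids, anything else (default
        "projected") for planar metre grids.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "projected"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def is_geographic(self) -> bool:
        return self.crs_tag == "geographic"

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (floor convention).

        Points outside the grid get indices outside ``[0, n_rows)`` /
        ``[0, n_cols)``; callers are expected to bounds-check.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def alignable_with(self, other: "GridSpec") -> bool:
        return self == other


@dataclass
class RasterLayer:
    """One named variable on a grid, with a nodata mask (True = missing)."""

    name: str
    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError(f"layer {self.name!r}: mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError(f"layer {self.name!r}: non-finite unmasked values")

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def with_values(self, values: np.ndarray, name: str | None = None,
                    mask: np.ndarray | None = None) -> "RasterLayer":
        return RasterLayer(
            name=self.name if name is None else name,
            grid=self.grid,
            values=values,
            mask=self.mask.copy() if mask is None else mask,
        )

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.name, self.grid, self.values.copy(), self.mask.copy())


class PredictorStack:
    """Ordered collection of layers sharing one grid.

    A cell masked in *any* layer is masked in stack-level queries
    (``combined_mask``), so training rows and predictions never see a
    partially observed cell.
    """

    def __init__(self, layers: Iterable[RasterLayer], period_tag: str = "historical"):
        self._layers: dict[str, RasterLayer] = {}
        self.period_tag = period_tag
        for layer in layers:
            self.add(layer)
        if not self._layers:
            raise ValueError("stack needs at least one layer")

    def add(self, layer: RasterLayer) -> None:
        if layer.name in self._layers:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        if self._layers:
            if layer.grid != self.grid:
                raise ValueError(f"layer {layer.name!r} not on the stack grid")
        self._layers[layer.name] = layer

    @property
    def grid(self) -> GridSpec:
        return next(iter(self._layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> RasterLayer:
        return self._layers[name]

    def __iter__(self) -> Iterator[RasterLayer]:
        return iter(self._layers.values())

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def combined_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        for layer in self._layers.values():
            mask |= layer.mask
        return mask

    def values_at(self, rows: np.ndarray, cols: np.ndarray,
                  names: Iterable[str] | None = None) -> "np.ndarray":
        """(n_points, n_layers) matrix of layer values at the given cells."""
        names = list(names) if names is not None else self.names
        out = np.empty((len(rows), len(names)), dtype=float)
        for j, name in enumerate(names):
            out[:, j] = self._layers[name].values[rows, cols]
        return out

    def to_frame(self, names: Iterable[str] | None = None):
        """All unmasked cells as a DataFrame plus their (rows, cols)."""
        import pandas as pd

        ok = ~self.combined_mask
        rows, cols = np.nonzero(ok)
        names = list(names) if names is not None else self.names
        data = {name: self._layers[name].values[rows, cols] for name in names}
        return pd.DataFrame(data), rows, cols

    def copy(self, period_tag: str | None = None) -> "PredictorStack":
        return PredictorStack(
            (l.copy() for l in self._layers.values()),
            period_tag=self.period_tag if period_tag is None else period_tag,
        )


# ---------------------------------------------------------------------------
# Terrain derivatives (Horn 3x3 stencil, borders masked)
# ---------------------------------------------------------------------------

def _horn_gradients(dem: RasterLayer) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interior Horn gradients (dz/dx eastward, dz/dy northward) and a
    validity mask. Border cells and cells touching nodata are invalid."""
    grid = dem.grid
    if grid.n_rows < 2 or grid.n_cols < 2:
        raise ValueError("gradient undefined on a degenerate grid")
    z = dem.values
    d = grid.cell_size
    gx = np.full(grid.shape, np.nan)
    gy = np.full(grid.shape, np.nan)
    # neighbour slices for interior cells; rows increase southwards
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx[1:-1, 1:-1] = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * d)
    gy[1:-1, 1:-1] = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * d)

    invalid = np.ones(grid.shape, dtype=bool)
    invalid[1:-1, 1:-1] = False
    # any masked cell poisons its 3x3 neighbourhood
    if dem.mask.any():
        from scipy.ndimage import binary_dilation

        invalid |= binary_dilation(dem.mask, structure=np.ones((3, 3), bool))
    return gx, gy, invalid


def compute_slope(dem: RasterLayer) -> RasterLayer:
    """Slope in degrees [0, 90] from a DEM using the Horn 3x3 stencil.

    Border cells and cells adjacent to nodata are masked.
    """
    gx, gy, invalid = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(np.nan_to_num(gx), np.nan_to_num(gy))))
    slope[invalid] = 0.0
    return RasterLayer("slope", dem.grid, slope, invalid)


def compute_aspect(dem: RasterLayer) -> RasterLayer:
    """Downslope azimuth in degrees [0, 360), 0 = north, clockwise.

    Flat cells (zero gradient) are masked in addition to borders/nodata.
    """
    gx, gy, invalid = _horn_gradients(dem)
    gx = np.nan_to_num(gx)
    gy = np.nan_to_num(gy)
    flat = (gx == 0.0) & (gy == 0.0)
    az = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    mask = invalid | flat
    az[mask] = 0.0
    return RasterLayer("aspect", dem.grid, az, mask)


def compute_trasp(aspect: RasterLayer, literal: bool = False) -> RasterLayer:
    """Transformed aspect, a 0–1 proxy for potential solar radiation load.

    The standard (Roberts–Cooper) form is ``(1 - cos((aspect - 30) deg)) / 2``:
    0 at 30 deg (cool NNE slopes), 1 at 210 deg (hot SSW slopes). With
    ``literal=True`` the alternative reading ``1 - cos(.)/2`` (range
    [0.5, 1.5]) is returned instead.
    """
    rad = np.radians(aspect.values - 30.0)
    if literal:
        vals = 1.0 - np.cos(rad) / 2.0
    else:
        vals = (1.0 - np.cos(rad)) / 2.0
    vals[aspect.mask] = 0.0
    return aspect.with_values(vals, name="trasp")


# ---------------------------------------------------------------------------
# Resampling and pixel area
# ---------------------------------------------------------------------------

def resample_nearest(src: RasterLayer, target: GridSpec) -> RasterLayer:
    """Nearest-neighbour resampling: each target cell takes the value of
    the source cell containing the target cell's center."""
    sx0, sy0, sx1, sy1 = src.grid.extent
    tx0, ty0, tx1, ty1 = target.extent
    if tx0 >= sx1 or tx1 <= sx0 or ty0 >= sy1 or ty1 <= sy0:
        raise ValueError("source and target extents are disjoint")
    xc = target.x_centers()
    yc = target.y_centers()
    xx, yy = np.meshgrid(xc, yc)
    rows, cols = src.grid.cell_of(xx.ravel(), yy.ravel())
    inside = (
        (rows >= 0)
        & (rows < src.grid.n_rows)
        & (cols >= 0)
        & (cols < src.grid.n_cols)
    )
    vals = np.zeros(rows.shape, dtype=float)
    mask = ~inside
    r = np.clip(rows, 0, src.grid.n_rows - 1)
    c = np.clip(cols, 0, src.grid.n_cols - 1)
    vals[inside] = src.values[r[inside], c[inside]]
    mask |= src.mask[r, c]
    vals[mask] = 0.0
    return RasterLayer(src.name, target,
                       vals.reshape(target.shape), mask.reshape(target.shape))


def pixel_area(grid: GridSpec, mode: str = "constant",
               ref_latitude: float | None = None) -> RasterLayer:
    """Per-cell area in km² as a layer named ``pixel_area``.

    constant
        Every cell gets the same area. Geographic grids use a spherical
        Earth (R = 6371 km): ``(R dphi) * (R dlam cos(ref_latitude))``
        with ``ref_latitude`` defaulting to the grid's central latitude.
        Projected grids ignore latitude entirely.
    per_latitude
        Geographic grids only; uses each cell-center latitude.
    """
    if mode not in ("constant", "per_latitude"):
        raise ValueError(f"unknown mode {mode!r}")
    if grid.is_geographic:
        dphi = math.radians(grid.cell_size)
        lat_centers = grid.y_centers()
        if np.any(np.abs(lat_centers) >= 90.0):
            raise ValueError("cell-center latitudes must lie in (-90, 90)")
        if mode == "constant":
            lat = float(np.mean(lat_centers)) if ref_latitude is None else ref_latitude
            if not -90.0 < lat < 90.0:
                raise ValueError("ref_latitude must lie in (-90, 90)")
            area = (EARTH_RADIUS_KM * dphi) ** 2 * math.cos(math.radians(lat))
            vals = np.full(grid.shape, area)
        else:
            col = (EARTH_RADIUS_KM * dphi) ** 2 * np.cos(np.radians(lat_centers))
            vals = np.repeat(col[:, None], grid.n_cols, axis=1)
    else:
        if mode == "per_latitude":
            raise ValueError("per_latitude area needs a geographic grid")
        vals = np.full(grid.shape, (grid.cell_size / 1000.0) ** 2)
    return RasterLayer("pixel_area", grid, vals)


def northing_layer(grid: GridSpec) -> RasterLayer:
    """Cell-center y coordinate as a layer (metres on projected grids)."""
    yy = np.repeat(grid.y_centers()[:, None], grid.n_cols, axis=1)
    return RasterLayer("northing", grid, yy)


# ---------------------------------------------------------------------------
# Plain-text raster I/O (ESRI ASCII grid + JSON stack manifest)
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (text, single band)."""
    grid = layer.grid
    path = Path(path)
    vals = np.where(layer.mask, _NODATA, layer.values)
    xll = grid.origin_x
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path, name: str | None = None,
                    crs_tag: str = "projected") -> RasterLayer:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows, n_cols, cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        crs_tag=crs_tag,
    )
    vals = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", _NODATA)
    mask = vals == nodata
    vals = np.where(mask, 0.0, vals)
    return RasterLayer(name or path.stem, grid, vals, mask)


def write_stack(stack: PredictorStack, directory: str | Path) -> Path:
    """Write every layer as an .asc file plus a JSON manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = {}
    for layer in stack:
        fname = f"{layer.name}.asc"
        write_ascii_grid(layer, directory / fname)
        entries[layer.name] = fname
    manifest = {
        "period_tag": stack.period_tag,
        "crs_tag": stack.grid.crs_tag,
        "layers": entries,
    }
    mpath = directory / "stack.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_stack(manifest_path: str | Path) -> PredictorStack:
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    layers = [
        read_ascii_grid(mpath.parent / fname, name=name,
                        crs_tag=manifest.get("crs_tag", "projected"))
        for name, fname in manifest["layers"].items()
    ]
    return PredictorStack(layers, period_tag=manifest.get("period_tag", "historical"))
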