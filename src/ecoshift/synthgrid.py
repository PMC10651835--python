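"""Synthetic landscapes: terrain, bioclimate, occurrences, scenarios, properties.

This module generates gridded study systems with the statistical structure
the suitability pipeline assumes about real mountain-west landscapes:

* a positive elevation surface with both a broad gradient and spatially
  autocorrelated relief;
* 19 bioclimate layers (named ``bio1`` .. ``bio19``) driven by a small set
  of latent fields (mean temperature, temperature range, annual
  precipitation, precipitation seasonality) so the layers are strongly
  collinear, as the real variables are. Temperature falls with elevation
  (lapse rate) and with northing; precipitation rises with elevation.
  Deterministic identities hold exactly: ``bio7 = bio5 - bio6``,
  ``bio5 >= bio6`` and ``bio12 >=`` every quarterly precipitation layer;
* occurrence plots labelled by a known logistic "truth" model, so
  downstream estimates can be compared against the generating process;
* additive/multiplicative climate-change scenarios that never touch
  terrain;
* a tiling of named, ownership-attributed property polygons (Voronoi
  cells clipped to the grid extent).

Every artifact is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .geoprep import GridSpec, PredictorStack, RasterLayer

__all__ = [
    "TruthModel",
    "ScenarioSpec",
    "PropertyPolygon",
    "BioclimConfig",
    "generate_terrain",
    "generate_bioclim",
    "generate_occurrences",
    "apply_scenario",
    "generate_properties",
    "TEMPERATURE_LAYERS",
    "PRECIPITATION_LAYERS",
]

#: bioclimate layers in degrees C (additive temperature deltas apply here)
TEMPERATURE_LAYERS = ("bio1", "bio5", "bio6", "bio8", "bio9", "bio10", "bio11")
#: bioclimate layers in mm
PRECIPITATION_LAYERS = ("bio12", "bio13", "bio14", "bio16", "bio17", "bio18", "bio19")

OWNERSHIP_CLASSES = ("FED", "PVT", "STAT", "TRIB")
AGENCIES = ("BLM", "FWS", "NPS", "USFS", "none")
STATES = ("AZ", "CO", "NM", "NV", "UT")


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially autocorrelated Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = f.std()
    if sd == 0:  # pragma: no cover - degenerate tiny grids only
        return f
    return (f - f.mean()) / sd


@dataclass(frozen=True)
class TruthModel:
    """Known data-generating suitability: logistic in standardized predictors.

    ``suitability = expit(intercept + sum coeff_j * z_j)`` where ``z_j`` is
    the predictor standardized over the unmasked cells of the historical
    stack. Coefficients therefore read as log-odds per standard deviation.
    """

    ecosystem_id: str
    predictor_coeffs: Mapping[str, float]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.predictor_coeffs.values()):
            raise ValueError("truth model needs at least one nonzero coefficient")

    @classmethod
    def calibrated(cls, ecosystem_id: str, predictor_coeffs: Mapping[str, float],
                   stack: PredictorStack, prevalence: float = 0.11,
                   tol: float = 1e-6) -> "TruthModel":
        """Truth model whose intercept is solved (bisection) so that mean
        suitability over the unmasked cells equals ``prevalence``.

        Fixing prevalence makes the rarity of the synthetic ecosystem a
        design constant instead of a by-product of the landscape draw.
        """
        if not 0.0 < prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        lo, hi = -40.0, 10.0
        for _ in range(80):
            mid = (lo + hi) / 2
            model = cls(ecosystem_id, predictor_coeffs, intercept=mid)
            s = model.suitability(stack)
            mean = float(s.values[~s.mask].mean())
            if abs(mean - prevalence) < tol:
                break
            if mean < prevalence:
                lo = mid
            else:
                hi = mid
        return cls(ecosystem_id, predictor_coeffs, intercept=(lo + hi) / 2)

    def suitability(self, stack: PredictorStack,
                    reference: PredictorStack | None = None) -> RasterLayer:
        """Truth suitability surface on ``stack``.

        ``reference`` supplies the standardization statistics (defaults to
        ``stack`` itself); pass the historical stack when evaluating truth
        on a scenario stack so the same scaling is used in both periods.
        """
        from scipy.special import expit

        ref = reference if reference is not None else stack
        ok = ~ref.combined_mask
        logit = np.full(stack.grid.shape, self.intercept, dtype=float)
        for name, coeff in self.predictor_coeffs.items():
            refvals = ref[name].values[ok]
            mu, sd = refvals.mean(), refvals.std()
            if sd == 0:
                raise ValueError(f"predictor {name!r} is constant in reference")
            logit += coeff * (stack[name].values - mu) / sd
        vals = expit(logit)
        mask = stack.combined_mask
        vals[mask] = 0.0
        return RasterLayer("truth_suitability", stack.grid, vals, mask)


@dataclass(frozen=True)
class ScenarioSpec:
    """One projection scenario: (GCM, SSP, period) label plus layer changes.

    ``deltas`` maps bioclimate layer names to additive offsets (degrees C or
    mm); ``factors`` maps layer names to multiplicative factors. Terrain
    layers may never appear in either. ``noise_sd`` adds a smooth,
    spatially correlated perturbation to every shifted layer.
    """

    gcm: str
    ssp: str
    period: str
    deltas: Mapping[str, float] = field(default_factory=dict)
    factors: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    @property
    def label(self) -> str:
        return f"{self.gcm}_{self.ssp}_{self.period}"


@dataclass
class PropertyPolygon:
    """One management property: identity, attribution and geometry."""

    property_id: str
    name: str
    state: str
    ownership: str
    agency: str
    geometry: object  # shapely geometry

    def __post_init__(self) -> None:
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise ValueError(f"property {self.property_id}: invalid geometry")


# ---------------------------------------------------------------------------
# Terrain and bioclimate
# ---------------------------------------------------------------------------

def generate_terrain(grid: GridSpec, seed: int,
                     relief: float = 700.0,
                     base_elevation: float = 1200.0,
                     north_rise: float = 1200.0,
                     east_rise: float = 300.0,
                     smoothness: float = 6.0) -> RasterLayer:
    """Strictly positive synthetic elevation (metres).

    The surface is a broad gradient rising ``north_rise`` metres south to
    north and ``east_rise`` west to east, plus a smoothed random field
    scaled to ``relief`` metres of relief, floored well above zero so
    lapse-rate couplings stay in realistic ranges.
    """
    if grid.n_rows < 20 or grid.n_cols < 20:
        raise ValueError("terrain generation expects a grid of at least 20x20")
    rng = np.random.default_rng(seed)
    ii, jj = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    ynorm = 1.0 - ii / (grid.n_rows - 1)  # 0 at south edge, 1 at north edge
    xnorm = jj / (grid.n_cols - 1)
    gradient = north_rise * ynorm + east_rise * xnorm
    rough = _smooth_field(grid.shape, rng, smoothness)
    elev = base_elevation + gradient + relief * rough
    elev = np.maximum(elev, 50.0)
    return RasterLayer("elevation", grid, elev)


@dataclass(frozen=True)
class BioclimConfig:
    """Couplings for the synthetic bioclimate (units: degrees C, mm, m).

    ``lapse_rate`` is degrees C of cooling per km of elevation;
    ``northing_cooling`` is the south-to-north temperature drop across the
    grid; ``layer_noise_sd`` is small independent smooth noise added per
    layer on top of the latent fields (keeps layers collinear but not
    degenerate).
    """

    sea_level_temp: float = 24.0
    lapse_rate: float = 6.5
    northing_cooling: float = 12.0
    temp_noise_sd: float = 2.5
    range_amplitude: float = 8.0
    base_precip: float = 250.0
    orographic_precip: float = 0.12  # mm per metre of elevation
    precip_noise_sd: float = 120.0
    layer_noise_sd: float = 0.3
    quarter_noise_sd: float = 3.0
    smoothness: float = 5.0


def generate_bioclim(elevation: RasterLayer, config: BioclimConfig | None = None,
                     seed: int = 0) -> PredictorStack:
    """19 collinear bioclimate layers + terrain derivatives as one stack.

    Four latent fields (mean temperature, temperature range, annual
    precipitation, precipitation seasonality) drive all 19 layers; the
    remaining variation is small smooth per-layer noise. The stack also
    carries ``elevation``, ``slope`` and ``trasp`` so it is directly
    usable as the model predictor set.
    """
    from .geoprep import compute_aspect, compute_slope, compute_trasp

    cfg = config or BioclimConfig()
    grid = elevation.grid
    rng = np.random.default_rng(seed)
    shape = grid.shape
    ii = np.arange(grid.n_rows)
    ynorm = 1.0 - ii / max(grid.n_rows - 1, 1)
    ynorm = np.repeat(ynorm[:, None], grid.n_cols, axis=1)

    def noise(sd: float) -> np.ndarray:
        return sd * _smooth_field(shape, rng, cfg.smoothness)

    elev = elevation.values
    # latent fields
    t_mean = (
        cfg.sea_level_temp
        - cfg.lapse_rate * elev / 1000.0
        - cfg.northing_cooling * ynorm
        + noise(cfg.temp_noise_sd)
    )
    # continentality: annual temperature range has its own strong spatial
    # structure, so extreme-month layers are not mere offsets of the mean
    t_range = np.clip(
        16.0 + cfg.range_amplitude * _smooth_field(shape, rng, cfg.smoothness)
        + noise(0.5), 4.0, None)
    p_annual = np.clip(
        cfg.base_precip + cfg.orographic_precip * elev + noise(cfg.precip_noise_sd),
        30.0, None,
    )
    p_season = np.clip(0.5 + 0.15 * _smooth_field(shape, rng, cfg.smoothness),
                       0.1, 0.9)

    ln = cfg.layer_noise_sd
    layers: dict[str, np.ndarray] = {}
    # annual mean carries its own station-scale noise; it is an estimate
    # of the latent mean climate, not the latent itself
    layers["bio1"] = t_mean + noise(1.2)
    layers["bio5"] = t_mean + 0.55 * t_range          # max temp, warmest month
    layers["bio6"] = layers["bio5"] - t_range         # min temp, coldest month
    layers["bio7"] = layers["bio5"] - layers["bio6"]  # annual range, exact
    layers["bio2"] = 0.45 * t_range + np.abs(noise(ln))
    layers["bio3"] = 100.0 * layers["bio2"] / layers["bio7"]
    layers["bio4"] = 100.0 * (0.30 * t_range + np.abs(noise(ln)))
    # quarterly means track the annual mean far more closely than the
    # monthly extremes do, so their loading on the range latent is small
    layers["bio8"] = t_mean + 0.10 * t_range + noise(cfg.quarter_noise_sd)
    layers["bio9"] = t_mean - 0.05 * t_range + noise(cfg.quarter_noise_sd)
    layers["bio10"] = t_mean + 0.15 * t_range + noise(cfg.quarter_noise_sd)
    layers["bio11"] = t_mean - 0.15 * t_range + noise(cfg.quarter_noise_sd)
    wet_q = np.clip(0.30 + 0.15 * p_season + noise(0.01), 0.05, 0.5)
    dry_q = np.clip(0.10 - 0.08 * p_season + np.abs(noise(0.005)), 0.01, 0.2)
    layers["bio12"] = p_annual
    layers["bio16"] = wet_q * p_annual
    layers["bio17"] = dry_q * p_annual
    layers["bio13"] = 0.45 * layers["bio16"]
    layers["bio14"] = 0.40 * layers["bio17"]
    layers["bio15"] = 100.0 * p_season
    layers["bio18"] = np.clip(0.25 + 0.10 * noise(1.0) / 3.0, 0.05, 0.45) * p_annual
    layers["bio19"] = np.clip(0.20 + 0.10 * noise(1.0) / 3.0, 0.05, 0.45) * p_annual

    stack_layers = [RasterLayer(f"bio{i}", grid, layers[f"bio{i}"])
                    for i in range(1, 20)]
    stack_layers.append(elevation.copy())
    slope = compute_slope(elevation)
    trasp = compute_trasp(compute_aspect(elevation))
    # terrain derivative masks (borders, flats) stay on those layers and are
    # handled by the stack-level combined mask
    stack_layers.append(slope)
    stack_layers.append(trasp)
    return PredictorStack(stack_layers, period_tag="historical")


# ---------------------------------------------------------------------------
# Occurrences and scenarios
# ---------------------------------------------------------------------------

def generate_occurrences(truth: TruthModel, stack: PredictorStack,
                         n_plots: int, seed: int):
    """Field plots labelled by the truth model; returns presences only.

    ``n_plots`` locations are drawn uniformly over the unmasked extent;
    each is retained as a presence with probability equal to the truth
    suitability of its cell (absences are discarded because the pipeline
    builds its own pseudo-absences). The returned DataFrame has columns
    ``plot_id, ecosystem_id, x, y`` and carries
    ``attrs['low_sample_warning'] = True`` when fewer than 50 presences
    survive, mirroring the minimum-record screen downstream.
    """
    import pandas as pd

    if n_plots < 50:
        raise ValueError("need at least 50 plots")
    rng = np.random.default_rng(seed)
    grid = stack.grid
    ok = ~stack.combined_mask
    suit = truth.suitability(stack).values
    xmin, ymin, xmax, ymax = grid.extent

    xs = np.empty(0)
    ys = np.empty(0)
    # rejection-sample plot locations on unmasked cells
    while xs.size < n_plots:
        m = int((n_plots - xs.size) * 1.5) + 16
        cx = rng.uniform(xmin, xmax, m)
        cy = rng.uniform(ymin, ymax, m)
        rows, cols = grid.cell_of(cx, cy)
        keep = ok[np.clip(rows, 0, grid.n_rows - 1),
                  np.clip(cols, 0, grid.n_cols - 1)]
        keep &= grid.contains(cx, cy)
        xs = np.concatenate([xs, cx[keep]])
        ys = np.concatenate([ys, cy[keep]])
    xs, ys = xs[:n_plots], ys[:n_plots]
    rows, cols = grid.cell_of(xs, ys)
    present = rng.random(n_plots) < suit[rows, cols]
    df = pd.DataFrame(
        {
            "plot_id": np.arange(n_plots)[present],
            "ecosystem_id": truth.ecosystem_id,
            "x": xs[present],
            "y": ys[present],
        }
    ).reset_index(drop=True)
    df.attrs["low_sample_warning"] = bool(present.sum() < 50)
    return df


def apply_scenario(stack: PredictorStack, spec: ScenarioSpec,
                   seed: int = 0) -> PredictorStack:
    """Shift bioclimate layers per the scenario; terrain is bit-identical.

    Additive deltas are applied first, then multiplicative factors, then
    smooth noise with SD ``spec.noise_sd``. Naming a layer absent from the
    stack, or a terrain layer, is an error.
    """
    rng = np.random.default_rng(seed)
    terrain = {"elevation", "slope", "trasp", "aspect"}
    touched = set(spec.deltas) | set(spec.factors)
    for name in touched:
        if name in terrain:
            raise ValueError(f"scenario may not alter terrain layer {name!r}")
        if name not in stack:
            raise ValueError(f"scenario names unknown layer {name!r}")
    out = []
    for layer in stack:
        if layer.name in touched:
            vals = layer.values.copy()
            vals += spec.deltas.get(layer.name, 0.0)
            vals *= spec.factors.get(layer.name, 1.0)
            if spec.noise_sd > 0:
                vals += spec.noise_sd * _smooth_field(layer.grid.shape, rng, 5.0)
            vals[layer.mask] = 0.0
            out.append(layer.with_values(vals))
        else:
            out.append(layer.copy())
    return PredictorStack(out, period_tag=spec.label)


def warming_scenario(gcm: str = "SYN-GCM1", ssp: str = "ssp370",
                     period: str = "2041-2060",
                     delta_t: float = 4.0, noise_sd: float = 0.0) -> ScenarioSpec:
    """Uniform warming applied to every degree-Celsius layer.

    Both monthly extremes shift equally, so the annual-range identity
    ``bio7 = bio5 - bio6`` is preserved.
    """
    return ScenarioSpec(
        gcm=gcm, ssp=ssp, period=period,
        deltas={name: delta_t for name in TEMPERATURE_LAYERS},
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# Property polygons
# ---------------------------------------------------------------------------

def generate_properties(grid: GridSpec, n_props: int,
                        seed: int) -> list[PropertyPolygon]:
    """Non-overlapping property polygons tiling the grid extent.

    Voronoi cells of ``n_props`` random seed points, clipped to the grid
    extent; each gets a state tag, an ownership class and (for Federal
    properties) a managing agency, drawn from the same seeded generator.
    """
    if n_props < 1:
        raise ValueError("need at least one property")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    extent = box(xmin, ymin, xmax, ymax)
    if n_props == 1:
        geoms = [extent]
    else:
        pts = MultiPoint(
            [
                Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
                for _ in range(n_props)
            ]
        )
        cells = voronoi_diagram(pts, envelope=extent)
        # voronoi_diagram order is not tied to input order; re-associate
        geoms = [None] * n_props
        clipped = [g.intersection(extent) for g in cells.geoms]
        for g in clipped:
            for i, p in enumerate(pts.geoms):
                if geoms[i] is None and g.contains(p):
                    geoms[i] = g
                    break
        geoms = [g for g in geoms if g is not None and not g.is_empty]
    props = []
    for i, geom in enumerate(geoms):
        ownership = OWNERSHIP_CLASSES[rng.integers(len(OWNERSHIP_CLASSES))]
        agency = AGENCIES[rng.integers(len(AGENCIES) - 1)] if ownership == "FED" else "none"
        props.append(
            PropertyPolygon(
                property_id=f"P{i:04d}",
                name=f"Property {i}",
                state=STATES[rng.integers(len(STATES))],
                ownership=ownership,
                agency=agency,
                geometry=geom,
            )
        )
    return props
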