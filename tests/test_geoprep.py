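"""Grid geometry, terrain derivatives, resampling and pixel areas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoshift.geoprep import (
    GridSpec,
    RasterLayer,
    PredictorStack,
    compute_aspect,
    compute_slope,
    compute_trasp,
    pixel_area,
    read_ascii_grid,
    read_stack,
    resample_nearest,
    write_ascii_grid,
    write_stack,
)


def horn_stencil_oracle(z, d):
    """Independent per-cell Horn gradient loop (no vectorization)."""
    n, m = z.shape
    gx = np.full((n, m), np.nan)
    gy = np.full((n, m), np.nan)
    for i in range(1, n - 1):
        for j in range(1, m - 1):
            a, b, c = z[i - 1, j - 1], z[i - 1, j], z[i - 1, j + 1]
            dd, f = z[i, j - 1], z[i, j + 1]
            g, h, k = z[i + 1, j - 1], z[i + 1, j], z[i + 1, j + 1]
            gx[i, j] = ((c + 2 * f + k) - (a + 2 * dd + g)) / (8 * d)
            gy[i, j] = ((a + 2 * b + c) - (g + 2 * h + k)) / (8 * d)
    return gx, gy


class TestGridSpec:
    def test_extent_and_centers(self, small_grid):
        xmin, ymin, xmax, ymax = small_grid.extent
        assert (xmax - xmin) == small_grid.n_cols * small_grid.cell_size
        assert small_grid.y_centers()[0] == ymax - small_grid.cell_size / 2
        # row 0 is northernmost
        assert small_grid.y_centers()[0] > small_grid.y_centers()[-1]

    def test_cell_of_is_inverse_of_center(self, small_grid):
        for row, col in [(0, 0), (3, 5), (9, 7)]:
            x, y = small_grid.center_of(row, col)
            r, c = small_grid.cell_of(x, y)
            assert (r, c) == (row, col)

    def test_half_open_cell_edges(self, small_grid):
        # a point on the shared vertical edge belongs to the right cell
        x_edge = small_grid.origin_x + 3 * small_grid.cell_size
        _, c = small_grid.cell_of(x_edge, small_grid.y_centers()[0])
        assert c == 3

    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            GridSpec(0, 5, 100.0)
        with pytest.raises(ValueError):
            GridSpec(5, 5, -1.0)


class TestSlopeAspect:
    def test_flat_dem_zero_slope(self, small_grid):
        dem = RasterLayer("elevation", small_grid,
                          np.full(small_grid.shape, 500.0))
        slope = compute_slope(dem)
        assert np.all(slope.values[~slope.mask] == 0.0)

    def test_unit_ramp_gives_45_degrees(self):
        grid = GridSpec(6, 6, 1.0, 0.0, 6.0)
        xx = np.arange(6, dtype=float)[None, :].repeat(6, axis=0)
        slope = compute_slope(RasterLayer("elevation", grid, xx))
        assert slope.values[2, 2] == pytest.approx(45.0)

    def test_aspect_cardinal_directions(self):
        grid = GridSpec(6, 6, 1.0, 0.0, 6.0)
        yy = np.arange(6, dtype=float)[:, None].repeat(6, axis=1)
        # values increase southwards -> terrain falls northwards
        aspect_north = compute_aspect(RasterLayer("elevation", grid, yy))
        assert aspect_north.values[2, 2] == pytest.approx(0.0)
        xx = np.arange(6, dtype=float)[None, :].repeat(6, axis=0)
        aspect_east = compute_aspect(RasterLayer("elevation", grid, -xx))
        assert aspect_east.values[2, 2] == pytest.approx(90.0)

    def test_matches_stencil_oracle(self, random_dem):
        gx, gy, = horn_stencil_oracle(random_dem.values,
                                      random_dem.grid.cell_size)[:2]
        slope = compute_slope(random_dem)
        aspect = compute_aspect(random_dem)
        interior = ~slope.mask
        expected_slope = np.degrees(np.arctan(np.hypot(gx, gy)))
        expected_aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
        assert np.allclose(slope.values[interior],
                           expected_slope[interior], atol=1e-9)
        assert np.allclose(aspect.values[interior & ~aspect.mask],
                           expected_aspect[interior & ~aspect.mask], atol=1e-9)

    def test_borders_masked(self, random_dem):
        slope = compute_slope(random_dem)
        assert slope.mask[0].all() and slope.mask[-1].all()
        assert slope.mask[:, 0].all() and slope.mask[:, -1].all()

    def test_degenerate_grid_errors(self):
        with pytest.raises(ValueError):
            compute_slope(RasterLayer("z", GridSpec(1, 1, 1.0), [[1.0]]))


class TestTrasp:
    @pytest.mark.parametrize("aspect_deg,expected",
                             [(30.0, 0.0), (210.0, 1.0), (120.0, 0.5)])
    def test_reference_angles(self, small_grid, aspect_deg, expected):
        aspect = RasterLayer("aspect", small_grid,
                             np.full(small_grid.shape, aspect_deg))
        assert compute_trasp(aspect).values[0, 0] == pytest.approx(expected)

    def test_literal_variant_range(self, small_grid):
        aspect = RasterLayer("aspect", small_grid,
                             np.full(small_grid.shape, 210.0))
        assert compute_trasp(aspect, literal=True).values[0, 0] == \
            pytest.approx(1.5)

    @given(st.floats(min_value=0.0, max_value=360.0 - 1e-9))
    @settings(deadline=None, max_examples=50)
    def test_periodic_and_bounded(self, a):
        grid = GridSpec(2, 2, 1.0)
        v1 = compute_trasp(
            RasterLayer("aspect", grid, np.full((2, 2), a))).values[0, 0]
        v2 = compute_trasp(
            RasterLayer("aspect", grid, np.full((2, 2), a + 360.0))).values[0, 0]
        assert v1 == pytest.approx(v2, abs=1e-9)
        assert 0.0 <= v1 <= 1.0
        # symmetry about the 30/210 axis
        v3 = compute_trasp(
            RasterLayer("aspect", grid, np.full((2, 2), 60.0 - a))).values[0, 0]
        assert v1 == pytest.approx(v3, abs=1e-9)


class TestResample:
    def test_identity_on_same_grid(self, random_dem):
        out = resample_nearest(random_dem, random_dem.grid)
        assert np.array_equal(out.values, random_dem.values)

    def test_constant_finer_source(self):
        src_grid = GridSpec(6, 6, 500.0, 0.0, 3000.0)
        tgt_grid = GridSpec(3, 3, 1000.0, 0.0, 3000.0)
        src = RasterLayer("v", src_grid, np.full((6, 6), 7.0))
        out = resample_nearest(src, tgt_grid)
        assert np.all(out.values == 7.0)

    def test_center_lookup_oracle(self, rng):
        src_grid = GridSpec(6, 6, 1000.0, 0.0, 6000.0)
        tgt_grid = GridSpec(3, 3, 2000.0, 0.0, 6000.0)
        src = RasterLayer("v", src_grid, rng.standard_normal((6, 6)))
        out = resample_nearest(src, tgt_grid)
        for i in range(3):
            for j in range(3):
                x, y = tgt_grid.center_of(i, j)
                r, c = src_grid.cell_of(x, y)
                assert out.values[i, j] == src.values[int(r), int(c)]

    def test_idempotent_on_own_grid(self, random_dem):
        tgt = GridSpec(5, 4, 2000.0, 0.0, 10_000.0)
        once = resample_nearest(random_dem, tgt)
        twice = resample_nearest(once, tgt)
        assert np.array_equal(once.values, twice.values)

    def test_disjoint_extents_error(self, random_dem):
        far = GridSpec(5, 5, 1000.0, 1e7, 1e7)
        with pytest.raises(ValueError):
            resample_nearest(random_dem, far)


class TestPixelArea:
    def test_quarter_degree_cell_at_39N(self):
        grid = GridSpec(10, 10, 2.5 / 60.0, -110.0, 40.0, crs_tag="geographic")
        layer = pixel_area(grid, mode="constant", ref_latitude=39.0)
        assert round(float(layer.values[0, 0]), 1) == 16.7

    def test_projected_constant(self):
        grid = GridSpec(3, 3, 4000.0)
        assert pixel_area(grid).values[1, 1] == pytest.approx(16.0)

    def test_per_latitude_cosine_ratio(self):
        # grid with cell centers exactly at 0 and 60 degrees latitude
        cs = 1.0
        grid = GridSpec(61, 4, cs, 0.0, 60.5, crs_tag="geographic")
        layer = pixel_area(grid, mode="per_latitude")
        lat = grid.y_centers()
        i0 = int(np.argmin(np.abs(lat - 0.0)))
        i60 = int(np.argmin(np.abs(lat - 60.0)))
        ratio = layer.values[i60, 0] / layer.values[i0, 0]
        assert ratio == pytest.approx(math.cos(math.radians(60.0)), abs=1e-9)

    def test_strictly_decreasing_with_latitude(self):
        grid = GridSpec(30, 3, 0.5, 0.0, 50.0, crs_tag="geographic")
        col = pixel_area(grid, mode="per_latitude").values[:, 0]
        assert np.all(np.diff(col) > 0)  # rows go south -> |lat| decreases

    def test_per_latitude_requires_geographic(self):
        with pytest.raises(ValueError):
            pixel_area(GridSpec(3, 3, 1000.0), mode="per_latitude")


class TestStackAndIO:
    def test_stack_combined_mask_unions_layers(self, small_grid, rng):
        m1 = np.zeros(small_grid.shape, bool)
        m2 = np.zeros(small_grid.shape, bool)
        m1[0, 0] = True
        m2[3, 3] = True
        stack = PredictorStack([
            RasterLayer("a", small_grid, rng.random(small_grid.shape), m1),
            RasterLayer("b", small_grid, rng.random(small_grid.shape), m2),
        ])
        assert stack.combined_mask[0, 0] and stack.combined_mask[3, 3]
        assert stack.combined_mask.sum() == 2

    def test_duplicate_layer_name_rejected(self, small_grid, rng):
        layer = RasterLayer("a", small_grid, rng.random(small_grid.shape))
        stack = PredictorStack([layer])
        with pytest.raises(ValueError):
            stack.add(layer.copy())

    def test_ascii_grid_roundtrip(self, tmp_path, random_dem):
        random_dem.mask[2, 3] = True
        write_ascii_grid(random_dem, tmp_path / "dem.asc")
        back = read_ascii_grid(tmp_path / "dem.asc", name="elevation")
        assert back.grid == random_dem.grid
        assert back.mask[2, 3]
        ok = ~back.mask
        assert np.array_equal(back.values[ok], random_dem.values[ok])

    def test_stack_roundtrip(self, tmp_path, small_grid, rng):
        stack = PredictorStack(
            [RasterLayer(n, small_grid, rng.random(small_grid.shape))
             for n in ("bio1", "bio12", "elevation")],
            period_tag="historical",
        )
        manifest = write_stack(stack, tmp_path / "stack")
        back = read_stack(manifest)
        assert back.names == stack.names
        assert back.period_tag == "historical"
        assert np.array_equal(back["bio12"].values, stack["bio12"].values)
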