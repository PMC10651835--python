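"""Area, elevation/northing migration and transition classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoshift.geoprep import GridSpec, RasterLayer, northing_layer, pixel_area
from ecoshift.shifts import (
    TRANSITION_CODES,
    SuitabilitySurface,
    classify_transitions,
    mean_position_of_suitable,
    percent_difference,
    suitability_area,
    summarize_shifts,
)

GRID = GridSpec(4, 4, 4000.0, origin_x=0.0, origin_y=16_000.0)
AREA = pixel_area(GRID)  # 16 km2 cells


def surface(values, period="historical", mask=None, eco="eco1"):
    return SuitabilitySurface(
        eco, period, RasterLayer("suitability", GRID,
                                 np.asarray(values, dtype=float), mask))


def full(value):
    return surface(np.full(GRID.shape, value))


class TestSuitabilityArea:
    def test_single_cell_product(self):
        vals = np.zeros(GRID.shape)
        vals[0, 0] = 0.5
        area_layer = RasterLayer("pixel_area", GRID,
                                 np.full(GRID.shape, 16.7))
        assert suitability_area(surface(vals), area_layer, 0.33) == \
            pytest.approx(0.5 * 16.7)

    def test_threshold_is_inclusive_boundary(self):
        assert suitability_area(full(0.32), AREA, 0.33) == 0.0
        assert suitability_area(full(0.33), AREA, 0.33) == \
            pytest.approx(0.33 * 16.0 * 16)

    def test_matches_bruteforce_loop(self, rng):
        vals = rng.random(GRID.shape)
        surf = surface(vals)
        expected = 0.0
        for i in range(4):
            for j in range(4):
                if vals[i, j] >= 0.33:
                    expected += vals[i, j] * AREA.values[i, j]
        assert suitability_area(surf, AREA, 0.33) == pytest.approx(
            expected, abs=1e-9)

    def test_monotone_in_threshold(self, rng):
        vals = rng.random(GRID.shape)
        surf = surface(vals)
        areas = [suitability_area(surf, AREA, t)
                 for t in (0.0, 0.16, 0.33, 0.5, 0.9)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_grid_mismatch_errors(self):
        other = pixel_area(GridSpec(3, 3, 4000.0))
        with pytest.raises(ValueError):
            suitability_area(full(0.5), other, 0.33)


class TestPercentDifference:
    def test_worked_examples(self):
        assert percent_difference(100.0, 180.0) == pytest.approx(80.0)
        assert percent_difference(100.0, 100.0) == 0.0

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 10.0)

    @given(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6))
    @settings(deadline=None, max_examples=50)
    def test_antisymmetry_identity(self, a, b):
        # pct(a,b) = -pct(b,a) * (b/a)
        assert percent_difference(a, b) == pytest.approx(
            -percent_difference(b, a) * (b / a), rel=1e-9)


class TestMeanPosition:
    def test_two_cell_average(self):
        vals = np.zeros(GRID.shape)
        vals[0, 0] = vals[1, 1] = 1.0
        elev = np.zeros(GRID.shape)
        elev[0, 0], elev[1, 1] = 100.0, 300.0
        out = mean_position_of_suitable(surface(vals),
                                        RasterLayer("elevation", GRID, elev),
                                        0.33)
        assert out == pytest.approx(200.0)

    def test_single_passing_cell(self):
        vals = np.zeros(GRID.shape)
        vals[2, 3] = 0.9
        northing = northing_layer(GRID)
        out = mean_position_of_suitable(surface(vals), northing, 0.33)
        assert out == northing.values[2, 3]

    def test_matches_filtered_mean_loop(self, rng):
        vals = rng.random(GRID.shape)
        pos = rng.random(GRID.shape) * 3000
        passing = [pos[i, j] for i in range(4) for j in range(4)
                   if vals[i, j] >= 0.33]
        out = mean_position_of_suitable(surface(vals),
                                        RasterLayer("p", GRID, pos), 0.33)
        assert out == pytest.approx(np.mean(passing), abs=1e-9)

    def test_no_passing_cell_errors(self):
        with pytest.raises(ValueError):
            mean_position_of_suitable(full(0.1), northing_layer(GRID), 0.33)


class TestTransitions:
    @pytest.mark.parametrize("hist,future,expected", [
        (0.4, 0.6, "high_increase"),
        (0.6, 0.4, "large_loss"),
        (0.2, 0.3, "moderate_increase"),
        (0.3, 0.2, "moderate_loss"),
        (0.2, 0.2, "unchanged"),
        (0.6, 0.9, "unchanged"),
    ])
    def test_rule_table(self, hist, future, expected):
        t = classify_transitions(full(hist), full(future))
        assert (t.classes == TRANSITION_CODES[expected]).all()

    def test_partitions_unmasked_cells(self, rng):
        h = surface(rng.random(GRID.shape))
        f = surface(rng.random(GRID.shape), period="future")
        t = classify_transitions(h, f)
        assert sum(t.counts().values()) == (~t.mask).sum()

    def test_swap_maps_gains_to_losses(self, rng):
        h = surface(rng.random(GRID.shape))
        f = surface(rng.random(GRID.shape), period="future")
        fwd = classify_transitions(h, f).classes
        rev = classify_transitions(f, h).classes
        swap = {TRANSITION_CODES["high_increase"]: TRANSITION_CODES["large_loss"],
                TRANSITION_CODES["large_loss"]: TRANSITION_CODES["high_increase"],
                TRANSITION_CODES["moderate_increase"]: TRANSITION_CODES["moderate_loss"],
                TRANSITION_CODES["moderate_loss"]: TRANSITION_CODES["moderate_increase"],
                TRANSITION_CODES["unchanged"]: TRANSITION_CODES["unchanged"]}
        assert np.array_equal(np.vectorize(swap.get)(fwd), rev)

    def test_matches_bruteforce_rules(self, rng):
        hv = rng.random(GRID.shape)
        fv = rng.random(GRID.shape)
        t = classify_transitions(surface(hv), surface(fv, period="future"))
        for i in range(4):
            for j in range(4):
                h, f = hv[i, j], fv[i, j]
                if f >= 0.5 and h < 0.5:
                    want = "high_increase"
                elif f < 0.5 and h >= 0.5:
                    want = "large_loss"
                elif 0.25 <= f < 0.5 and h < 0.25:
                    want = "moderate_increase"
                elif f < 0.25 and 0.25 <= h < 0.5:
                    want = "moderate_loss"
                else:
                    want = "unchanged"
                assert t.classes[i, j] == TRANSITION_CODES[want]


class TestSummarize:
    def test_identical_future_gives_zero_pct(self, rng):
        vals = rng.random(GRID.shape)
        surfaces = {"historical": surface(vals),
                    "gcm_ssp370_2050": surface(vals, period="gcm_ssp370_2050")}
        dem = RasterLayer("elevation", GRID, 1000 + 500 * rng.random(GRID.shape))
        out = summarize_shifts("eco1", surfaces, dem, AREA,
                               northing_layer(GRID))
        assert len(out) == 1
        s = out[0]
        assert s.pct_area_diff == 0.0
        assert s.pct_elev_diff == 0.0
        assert s.pct_northing_diff == 0.0

    def test_threshold_override_applied(self, rng):
        vals = np.full(GRID.shape, 0.2)
        surfaces = {"historical": surface(vals),
                    "f": surface(vals, period="f")}
        dem = RasterLayer("elevation", GRID, np.full(GRID.shape, 1000.0))
        out = summarize_shifts("savanna", surfaces, dem, AREA,
                               northing_layer(GRID), threshold=0.33,
                               threshold_overrides={"savanna": 0.16})
        assert out[0].threshold_used == 0.16
        assert out[0].area_hist > 0

    def test_missing_historical_errors(self):
        with pytest.raises(ValueError):
            summarize_shifts("e", {"f": full(0.5)},
                             RasterLayer("elevation", GRID,
                                         np.ones(GRID.shape)),
                             AREA, northing_layer(GRID))

    def test_uniform_upscaling_nonnegative_pct(self, rng):
        vals = 0.34 + 0.3 * rng.random(GRID.shape)
        doubled = np.clip(vals * 1.5, 0, 1)
        surfaces = {"historical": surface(vals),
                    "f": surface(doubled, period="f")}
        dem = RasterLayer("elevation", GRID, np.full(GRID.shape, 1000.0))
        out = summarize_shifts("e", surfaces, dem, AREA, northing_layer(GRID))
        assert out[0].pct_area_diff >= 0.0
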