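"""Envelope construction, pseudo-absences, dedup and stratified split."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from ecoshift.geoprep import GridSpec, PredictorStack, RasterLayer
from ecoshift.sampling import (
    SamplingConfig,
    TrainingTable,
    assemble_table,
    build_envelope,
    draw_pseudo_absences,
    filter_ecosystem,
)

GRID = GridSpec(50, 50, 4000.0, origin_x=0.0, origin_y=200_000.0)
STUDY_AREA = box(*GRID.extent)


def records_at(points, ecosystem="eco1"):
    return pd.DataFrame({
        "plot_id": range(len(points)),
        "ecosystem_id": ecosystem,
        "x": [p[0] for p in points],
        "y": [p[1] for p in points],
    })


def simple_stack(rng=None):
    rng = rng or np.random.default_rng(0)
    layers = [RasterLayer(n, GRID, rng.random(GRID.shape))
              for n in ("bio1", "bio5", "elevation")]
    return PredictorStack(layers)


class TestFilterEcosystem:
    def test_distinct_cell_threshold(self):
        # 49 distinct cells -> rejected; 50 -> accepted
        pts49 = [GRID.center_of(i // 7, i % 7) for i in range(49)]
        pts50 = [GRID.center_of(i // 8, i % 8) for i in range(50)]
        ok49, n49 = filter_ecosystem(records_at(pts49), GRID)
        ok50, n50 = filter_ecosystem(records_at(pts50), GRID)
        assert (ok49, n49) == (False, 49)
        assert (ok50, n50) == (True, 50)

    def test_redundant_records_count_once(self):
        # 120 records piled into 40 cells
        pts = [GRID.center_of(i % 40 // 8, i % 40 % 8) for i in range(120)]
        ok, n = filter_ecosystem(records_at(pts), GRID)
        assert (ok, n) == (False, 40)

    def test_empty_input_rejected_with_zero(self):
        ok, n = filter_ecosystem(records_at([]), GRID)
        assert (ok, n) == (False, 0)


class TestEnvelope:
    def test_single_interior_record_is_disk(self):
        records = records_at([(100_000.0, 100_000.0)])
        cfg = SamplingConfig(buffer_radius_km=20.0)
        env = build_envelope(records, STUDY_AREA, cfg)
        assert env.area == pytest.approx(math.pi * 20_000.0**2, rel=5e-3)

    def test_far_apart_records_give_two_disks(self):
        records = records_at([(40_000.0, 100_000.0), (160_000.0, 100_000.0)])
        cfg = SamplingConfig(buffer_radius_km=20.0)
        env = build_envelope(records, STUDY_AREA, cfg)
        assert env.area == pytest.approx(2 * math.pi * 20_000.0**2, rel=5e-3)

    def test_boundary_record_clipped(self):
        records = records_at([(0.0, 100_000.0)])
        cfg = SamplingConfig(buffer_radius_km=20.0)
        env = build_envelope(records, STUDY_AREA, cfg)
        assert env.area < math.pi * 20_000.0**2


class TestPseudoAbsences:
    def test_all_points_inside_envelope(self):
        records = records_at([(100_000.0, 100_000.0)])
        cfg = SamplingConfig(n_pseudo=500, buffer_radius_km=30.0)
        env = build_envelope(records, STUDY_AREA, cfg)
        pts = draw_pseudo_absences(env, cfg, seed=1)
        assert len(pts) == 500
        assert shapely.contains_xy(env, pts["x"], pts["y"]).all()

    def test_seeded_determinism(self):
        records = records_at([(100_000.0, 100_000.0)])
        cfg = SamplingConfig(n_pseudo=200, buffer_radius_km=30.0)
        env = build_envelope(records, STUDY_AREA, cfg)
        a = draw_pseudo_absences(env, cfg, seed=9)
        b = draw_pseudo_absences(env, cfg, seed=9)
        assert a.equals(b)

    def test_uniform_density_chi2(self):
        """Quadrat chi-square on a square envelope: no spatial preference."""
        from scipy.stats import chi2

        env = box(0.0, 0.0, 80_000.0, 80_000.0)
        cfg = SamplingConfig(n_pseudo=2500)
        pts = draw_pseudo_absences(env, cfg, seed=3)
        bins = np.linspace(0, 80_000.0, 5)
        counts, _, _ = np.histogram2d(pts["x"], pts["y"], bins=[bins, bins])
        expected = 2500 / 16
        stat = ((counts - expected) ** 2 / expected).sum()
        assert stat < chi2.ppf(0.99, df=15)

    def test_degenerate_envelope_rejected(self):
        with pytest.raises(ValueError):
            draw_pseudo_absences(box(0, 0, 1, 1).intersection(box(5, 5, 6, 6)),
                                 SamplingConfig())


class TestAssembleTable:
    def test_presence_supersedes_absence_in_shared_cell(self):
        stack = simple_stack()
        x, y = GRID.center_of(10, 10)
        pres = records_at([(x, y)])
        pa = pd.DataFrame({"x": [x + 1.0, *(GRID.center_of(i, 0) for i in range(3))][0:1],
                           "y": [y - 1.0]})
        # add distinct absence cells so both labels survive
        extra = pd.DataFrame({"x": [GRID.center_of(1, 1)[0], GRID.center_of(2, 2)[0]],
                              "y": [GRID.center_of(1, 1)[1], GRID.center_of(2, 2)[1]]})
        pa = pd.concat([pa, extra], ignore_index=True)
        table = assemble_table(pres, pa, stack, SamplingConfig(seed=0))
        cell = table.df[(table.df.cell_row == 10) & (table.df.cell_col == 10)]
        assert len(cell) == 1
        assert cell["label"].iloc[0] == 1

    def test_multiple_presences_one_row(self):
        stack = simple_stack()
        x, y = GRID.center_of(5, 5)
        pres = records_at([(x, y), (x + 10, y - 10), (x - 10, y + 10)])
        pa = pd.DataFrame({"x": [GRID.center_of(1, 1)[0]],
                           "y": [GRID.center_of(1, 1)[1]]})
        table = assemble_table(pres, pa, stack, SamplingConfig(seed=0))
        assert (table.df.label == 1).sum() == 1

    def test_exact_stratified_counts(self):
        """100 presences + 2500 absences at 0.8 -> 80/2000 train, 20/500 test."""
        stack = simple_stack()
        pres_pts = [GRID.center_of(i // 10, i % 10) for i in range(100)]
        pa_pts = [GRID.center_of(10 + i // 40, i % 40) for i in range(2500)]
        # absences on distinct rows 10.. so no collision with presences
        pres = records_at(pres_pts)
        pa = pd.DataFrame({"x": [p[0] for p in pa_pts],
                           "y": [p[1] for p in pa_pts]})
        table = assemble_table(pres, pa, stack, SamplingConfig(seed=1))
        # 2500 points in 40x40 cells collide; use distinct-cell counts
        n_pres = (table.df.label == 1).sum()
        n_abs = (table.df.label == 0).sum()
        assert n_pres == 100
        tr, te = table.train, table.test
        assert len(tr) + len(te) == len(table.df)
        assert (tr.label == 1).sum() == round(0.8 * n_pres)
        assert (te.label == 1).sum() == n_pres - round(0.8 * n_pres)
        assert (tr.label == 0).sum() == round(0.8 * n_abs)

    def test_split_is_partition(self):
        stack = simple_stack()
        pres = records_at([GRID.center_of(i, i) for i in range(30)])
        pa = pd.DataFrame({"x": [GRID.center_of(i, 0)[0] for i in range(1, 31)],
                           "y": [GRID.center_of(i, 0)[1] for i in range(1, 31)]})
        table = assemble_table(pres, pa, stack, SamplingConfig(seed=2))
        assert set(table.df.partition) == {"train", "test"}
        key = table.df[["cell_row", "cell_col"]].apply(tuple, axis=1)
        assert key.is_unique

    def test_masked_cells_dropped(self):
        rng = np.random.default_rng(0)
        mask = np.zeros(GRID.shape, bool)
        mask[3, 3] = True
        layers = [RasterLayer("bio1", GRID, rng.random(GRID.shape), mask),
                  RasterLayer("bio5", GRID, rng.random(GRID.shape))]
        stack = PredictorStack(layers)
        pres = records_at([GRID.center_of(3, 3), GRID.center_of(4, 4)])
        pa = pd.DataFrame({"x": [GRID.center_of(6, 6)[0]],
                           "y": [GRID.center_of(6, 6)[1]]})
        table = assemble_table(pres, pa, stack, SamplingConfig(seed=0))
        assert not ((table.df.cell_row == 3) & (table.df.cell_col == 3)).any()

    def test_single_label_after_dedup_errors(self):
        stack = simple_stack()
        x, y = GRID.center_of(7, 7)
        pres = records_at([(x, y)])
        pa = pd.DataFrame({"x": [x + 5.0], "y": [y - 5.0]})  # same cell
        with pytest.raises(ValueError):
            assemble_table(pres, pa, stack, SamplingConfig(seed=0))

    def test_csv_roundtrip(self, tmp_path):
        stack = simple_stack()
        pres = records_at([GRID.center_of(i, i) for i in range(10)])
        pa = pd.DataFrame({"x": [GRID.center_of(i, 0)[0] for i in range(1, 11)],
                           "y": [GRID.center_of(i, 0)[1] for i in range(1, 11)]})
        table = assemble_table(pres, pa, stack, SamplingConfig(seed=3))
        path = tmp_path / "table.csv"
        table.save(path)
        back = TrainingTable.load(path)
        assert back.predictors == table.predictors
        assert back.grid == table.grid
        pd.testing.assert_frame_equal(back.df, table.df.reset_index(drop=True))
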