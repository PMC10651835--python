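import numpy as np
import pytest

from ecoshift.geoprep import GridSpec, RasterLayer, PredictorStack


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_grid():
    """10x8 projected grid of 1 km cells."""
    return GridSpec(n_rows=10, n_cols=8, cell_size=1000.0,
                    origin_x=0.0, origin_y=10_000.0)


@pytest.fixture
def random_dem(small_grid, rng):
    return RasterLayer("elevation", small_grid,
                       1000.0 + 200.0 * rng.standard_normal(small_grid.shape))


@pytest.fixture(scope="session")
def landscape_stack():
    """Small full landscape shared by read-only tests (30x30, 4 km cells)."""
    from ecoshift.experiments import build_landscape
    from ecoshift.geoprep import GridSpec

    grid = GridSpec(30, 30, 4000.0, origin_x=300_000.0, origin_y=4_200_000.0)
    return build_landscape(seed=7, grid=grid)


def make_layer(grid, values, name="layer", mask=None):
    return RasterLayer(name, grid, np.asarray(values, dtype=float), mask)
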