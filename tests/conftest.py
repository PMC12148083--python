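import numpy as np
import pytest

from paleowalk.cost_surface import CostSurface
from paleowalk.raster_core import GridRaster
from paleowalk.synthetic_landscape import SynthConfig, make_landscape, make_uniform_plain


@pytest.fixture
def flat_dem() -> GridRaster:
    return GridRaster(np.full((20, 20), 100.0))


@pytest.fixture
def wet_precip() -> GridRaster:
    return GridRaster(np.full((20, 20), 600.0))


@pytest.fixture
def uniform_plain() -> CostSurface:
    return make_uniform_plain(50)


@pytest.fixture(scope="session")
def small_landscape() -> dict:
    """Full synthetic layer stack, small enough for sub-second builds."""
    return make_landscape(SynthConfig(n_rows=60, n_cols=60, seed=7))


def random_raster(rng: np.random.Generator, shape=(8, 6), nodata_frac=0.1) -> GridRaster:
    vals = rng.normal(50.0, 20.0, shape)
    vals[rng.random(shape) < nodata_frac] = -9999.0
    return GridRaster(
        vals,
        cell_size_km=float(rng.choice([0.5, 1.0, 2.0])),
        origin_xy=(float(rng.uniform(-100, 100)), float(rng.uniform(-100, 100))),
    )
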