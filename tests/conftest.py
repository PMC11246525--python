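import numpy as np
import pytest

from wheatcast.raster import GridSpec, RasterGrid
from wheatcast.synthdata import SceneConfig, generate_scene


@pytest.fixture
def spec10() -> GridSpec:
    return GridSpec(0.0, 10.0, 1.0, 1.0, 10, 10, "test")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def grid_from(spec: GridSpec, values, valid=None) -> RasterGrid:
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return RasterGrid(spec, values, np.asarray(valid, bool))


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """A reduced scene used by several integration tests: 9 counties x 4
    seasons on a 48x48 grid with an 8x coarse sensor."""
    return SceneConfig(
        n_rows=48, n_cols=48, n_counties=9, n_years=4,
        coarse_factor=8, climate_factor=16, n_sites=5,
        spatial_corr_length=8.0, cloud_corr_length=6.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)
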