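import numpy as np
import pytest

from nichediverge.grid_io import Grid, GridHeader, LayerStack


@pytest.fixture
def header():
    return GridHeader(ncols=5, nrows=4, xllcorner=-10.0, yllcorner=40.0, cellsize=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_stack(header, rng):
    """Two fully valid random layers on the shared 4x5 header."""
    layers = [
        Grid(header, rng.normal(size=(4, 5)), np.ones((4, 5), bool)),
        Grid(header, rng.normal(size=(4, 5)), np.ones((4, 5), bool)),
    ]
    return LayerStack(["env_1", "env_2"], layers)


def random_masked_grid(rng, nrows=6, ncols=7, nodata=-9999.0, p_masked=0.2):
    header = GridHeader(
        ncols=ncols, nrows=nrows,
        xllcorner=float(rng.uniform(-100, 0)),
        yllcorner=float(rng.uniform(0, 50)),
        cellsize=float(rng.uniform(0.01, 2.0)),
        nodata_value=nodata,
    )
    values = rng.normal(size=(nrows, ncols)) * 10
    mask = rng.uniform(size=(nrows, ncols)) > p_masked
    values = np.where(mask, values, nodata)
    return Grid(header, values, mask)
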