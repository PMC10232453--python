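import numpy as np
import pytest

from vhiopt import GridSpec, RasterCube


@pytest.fixture
def grid4() -> GridSpec:
    """A 4x4 geographic grid, 0.5-degree pixels, NW corner at (10E, 52N)."""
    return GridSpec(4, 4, 10.0, 52.0, 0.5, 0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230531)


def make_cube(values, times=None, valid=None, grid=None, freq="annual") -> RasterCube:
    values = np.asarray(values, dtype=float)
    nt, nr, nc = values.shape
    if grid is None:
        grid = GridSpec(nr, nc, 0.0, float(nr), 1.0, 1.0)
    if times is None:
        times = list(range(2000, 2000 + nt))
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return RasterCube(grid, list(times), values, valid, freq=freq)


@pytest.fixture
def make_cube_factory():
    return make_cube
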