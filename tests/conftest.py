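import numpy as np
import pytest

from dbarnet.grids import ImageGrid, PlaneGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def solver_grid():
    return PlaneGrid(64, 1.05)


@pytest.fixture(scope="session")
def image_grid():
    return ImageGrid(64)


def radial_test_sigma(grid, amplitude=0.5, rho=0.4, width=0.15):
    """The package's canonical smooth radial phantom (contrast 1.5)."""
    r = np.abs(grid.z)
    return 1.0 + amplitude * 0.5 * (1.0 - np.tanh((r - rho) / width))


@pytest.fixture(scope="session")
def radial_sigma():
    return radial_test_sigma
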