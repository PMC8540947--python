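import numpy as np
import pytest

from onmftv import SpatialGrid, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid3x3():
    return SpatialGrid.full(3, 3)


def chain_grid(n: int) -> SpatialGrid:
    """1-D chain of n pixels (a single grid row)."""
    return SpatialGrid(np.column_stack([np.zeros(n, int), np.arange(n)]))


@pytest.fixture(scope="session")
def small_phantom():
    """12x12 grid, 3 classes, 30 channels, mild noise — fast solver fixture."""
    return make_phantom(
        height=12, width=12, n_clusters=3, n_channels=30, snr=4.0,
        contamination=0.05, minority_fraction=None, seed=7,
    )


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Exactly factorizable phantom: X = U* V*, well-separated signatures."""
    return make_phantom(
        height=10, width=10, n_clusters=3, n_channels=24, snr=np.inf,
        minority_fraction=None, seed=3,
    )
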