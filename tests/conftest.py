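import numpy as np
import pytest

from morphoblocks import SimulationParams, simulate_dataset
from morphoblocks.io_tps import PairMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pair_map():
    # 8 landmarks: 2 midline + 3 bilateral pairs
    return PairMap(((2, 3), (4, 5), (6, 7)), (0, 1))


def small_params(**overrides) -> SimulationParams:
    """Reduced-size study conditions for fast unit tests."""
    defaults = dict(
        n_per_block=(8, 6, 6, 8),
        k_per_view=(11, 12, 9),
        n_localities=8,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture
def small_dataset():
    return simulate_dataset(small_params())


@pytest.fixture(scope="session")
def paper_size_dataset():
    """One dataset at the full study sizes (89 specimens, 3 views)."""
    return simulate_dataset(SimulationParams(seed=7))


def random_config(rng, k=10, scale=1.0):
    return rng.normal(size=(k, 2)) * scale
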