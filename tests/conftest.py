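import numpy as np
import pytest

from sirtsim import build_lattice, deposit, sample_cluster_sizes


@pytest.fixture(scope="session")
def small_model():
    """1 g liver block (500 lobules, single layer)."""
    return build_lattice(1000.0)


@pytest.fixture(scope="session")
def mid_model():
    """16 g liver block, 12 mm deep."""
    return build_lattice(16000.0, lobules_per_layer=1000)


@pytest.fixture(scope="session")
def small_deposition(small_model):
    """Dense structured deposition on the 1 g block (~150 Bq/mg)."""
    sizes = sample_cluster_sizes(3000, rng_seed=11)
    return deposit(small_model, sizes, rng_seed=12, exclusive_tracts=False)


@pytest.fixture(scope="session")
def deep_deposition(mid_model):
    """Structured deposition on the 16 g / 12 mm-deep block."""
    sizes = sample_cluster_sizes(96_000, rng_seed=19)
    return deposit(mid_model, sizes, rng_seed=19, exclusive_tracts=False)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
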