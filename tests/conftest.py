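import numpy as np
import pytest

from emscore import DensityMap, make_toy_structure


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_map_pair(rng):
    """Two independent random 8x8x8 maps on the same grid."""
    a = DensityMap(rng.random((8, 8, 8)), apix=1.0)
    b = DensityMap(rng.random((8, 8, 8)), apix=1.0)
    return a, b


@pytest.fixture
def helix():
    return make_toy_structure(10, "helix", seed=0)


@pytest.fixture
def helix40():
    return make_toy_structure(40, "helix", seed=0)
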