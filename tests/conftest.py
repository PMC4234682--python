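import numpy as np
import pytest

from gamutrel import MappingConfig, RegionMap


@pytest.fixture
def cfg():
    return MappingConfig()


@pytest.fixture
def simple_map():
    """A 4x6 map with three regions: dark surround, mid target, bright patch.

    Region 0: 10 cd/m^2 surround; region 1: 40 cd/m^2 target strip;
    region 2: 80 cd/m^2 patch touching the surround only.
    """
    lum = np.full((4, 6), 10.0)
    labels = np.zeros((4, 6), dtype=int)
    lum[1:3, 1:3] = 40.0
    labels[1:3, 1:3] = 1
    lum[1:3, 4:6] = 80.0
    labels[1:3, 4:6] = 2
    return RegionMap(lum, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
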