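import numpy as np
import pytest

from hepaquant import SceneSpec
from hepaquant.benchmarks import analyse_scene
from hepaquant.geometry import FovGeometry


@pytest.fixture
def geom():
    return FovGeometry(256, 256, 0.5)


@pytest.fixture
def geom_large():
    return FovGeometry(512, 512, 0.5)


@pytest.fixture(scope="session")
def pck_scene():
    """One analysed PCK-IHC FOV shared across tests: (cells, truth, maps,
    od_triple, labels) for the default 512 px scene."""
    spec = SceneSpec(seed=42)
    return analyse_scene(spec), spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
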