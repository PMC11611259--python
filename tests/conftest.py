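import numpy as np
import pytest

from gvsim.afferent import default_tf_bank
from gvsim.fusion import FusionParams
from gvsim.geometry import default_canal_basis
from gvsim.observer import ObserverParams


@pytest.fixture(scope="session")
def tf_bank():
    return default_tf_bank()


@pytest.fixture(scope="session")
def basis():
    return default_canal_basis()


@pytest.fixture(scope="session")
def trained_fusion():
    """Trained operating point: irregular-only dynamics, K_GVS = 0.0245."""
    return FusionParams()


@pytest.fixture(scope="session")
def observer_params():
    return ObserverParams()


@pytest.fixture(scope="session")
def coarse_observer():
    """Coarser integration step for tests where 0.02 s resolution suffices."""
    return ObserverParams(dt=0.02)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
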