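import numpy as np
import pytest

from dendrosoma.soma import SomaModel, morris_lecar_soma
from dendrosoma.system import ds_system


@pytest.fixture(scope="session")
def ml_soma():
    return morris_lecar_soma()


@pytest.fixture(scope="session")
def passive_soma():
    """Leak-only soma: every active conductance absent."""
    return SomaModel(C_sigma=20.0, G_sigma=2.0, E_L=-60.0)


@pytest.fixture(scope="session")
def snic_system():
    """DS system deep in the SNIC regime (G_in = 3 nS, tau_delta = 5 ms)."""
    return ds_system(3.0, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
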