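import numpy as np
import pytest

from anisowomersley.constitutive import AnisotropyRatios
from anisowomersley.spectral import cgl_grid


@pytest.fixture(scope="session")
def grid150():
    return cgl_grid(150)


@pytest.fixture(scope="session")
def grid20():
    return cgl_grid(20)


@pytest.fixture(scope="session")
def iso():
    return AnisotropyRatios()


@pytest.fixture(scope="session")
def aniso():
    """The anisotropy used throughout the study protocols (beta = gamma = 0.1)."""
    return AnisotropyRatios(beta=0.1, gamma=0.1, delta=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
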