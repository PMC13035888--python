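import numpy as np
import pytest

from indentfit.constitutive import HyperelasticParams
from indentfit.invfit import ForwardModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def coarse_forward():
    """Shared coarse-mesh forward model (caches solves across tests)."""
    return ForwardModel(preset="coarse", n_steps=8)


def random_stable_yeoh(rng: np.random.Generator) -> HyperelasticParams:
    """Positive Yeoh coefficients, log-uniform in [1e-4, 1e-2] N/mm^2.

    Positivity of all three coefficients makes the tangent positive
    definite in every mode, so these sets are Drucker stable by
    construction.
    """
    C = 10.0 ** rng.uniform(-4, -2, size=3)
    return HyperelasticParams("yeoh", C=tuple(C))
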