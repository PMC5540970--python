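import numpy as np
import pytest

from etsim import ModelParameters


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """The published default parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def exp_grid() -> np.ndarray:
    """Sampling grid (h) of the published cytokine time-course assays."""
    return np.array([1.0, 2.0, 4.0, 8.0, 16.0, 24.0])
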