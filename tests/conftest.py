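import numpy as np
import pytest

from smcondense import synthgen


@pytest.fixture
def polymer():
    """Default 13,552-nt chain with a 2 pN half-force."""
    return synthgen.PolymerModel()


@pytest.fixture
def dense_schedule():
    """Fine force grid spanning ~0 to the common 17.5 pN ceiling."""
    return np.linspace(0.05, 17.5, 1000)


@pytest.fixture
def coarse_schedule():
    return np.linspace(0.1, 17.5, 40)
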