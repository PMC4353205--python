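import numpy as np
import pytest

from effortrl import ModelParams


@pytest.fixture
def baseline():
    """Baseline learning/choice parameters used across the simulations."""
    return ModelParams(seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(987)
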