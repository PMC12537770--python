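import numpy as np
import pytest

from lvtrio import InteractionMatrix, default_community


@pytest.fixture
def community():
    """Representative (E, Y, B) parameter set used throughout."""
    return default_community()


@pytest.fixture
def weak_alphas():
    """Near-neutral interactions (the non-interacting baseline)."""
    a = 0.01
    return InteractionMatrix(
        alpha_EY=a, alpha_EB=a, alpha_YE=a, alpha_YB=a, alpha_BE=a, alpha_BY=a
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
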