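import numpy as np
import pytest

from breathfield.simulation import (
    BreathingModel,
    SequenceSpec,
    make_phantom,
    make_sensitivities,
    make_trace,
)


@pytest.fixture(scope="session")
def phantom32():
    """Small 32×32, 3-slice phantom for fast recon tests."""
    return make_phantom(matrix=32, n_slices=3, seed=0)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(matrix=64, n_slices=8, seed=0)


@pytest.fixture(scope="session")
def sens32(phantom32):
    return make_sensitivities(phantom32, n_coils=4)


@pytest.fixture()
def breathing_model():
    return BreathingModel(period_sd_s=0.0)


@pytest.fixture()
def short_trace():
    return make_trace(40.0, period_mean_s=4.5, period_sd_s=0.0, seed=3)


@pytest.fixture()
def megre32_spec():
    return SequenceSpec.megre(matrix=(32, 32))


def rng(seed=0):
    return np.random.default_rng(seed)
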