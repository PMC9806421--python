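import numpy as np
import pytest

from statekin.channel import ChannelModel, RateSpec, default_model


@pytest.fixture(scope="session")
def model():
    """The calibrated default channel model."""
    return default_model()


@pytest.fixture
def two_state_model():
    """Effectively two-state toy: R <-> FI with rates a, b.

    O and SI are given fast escape routes and no inflow, so they carry no
    stationary mass and the unbound chain reduces to R <-> FI.
    """
    a, b = 3.0, 7.0
    return ChannelModel(
        rates={
            ("R", "FI"): RateSpec(a),
            ("FI", "R"): RateSpec(b),
            ("O", "R"): RateSpec(1e3),
            ("SI", "FI"): RateSpec(1e3),
        },
        k_assoc={"R": 0.0, "O": 0.0, "FI": 0.0, "SI": 0.0},
        k_off=1.0,
    ), a, b


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
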