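import numpy as np
import pytest

from tomovsm.synth import SynthModelParams, make_synthetic_model
from tomovsm.transport import TransportConfig


@pytest.fixture(scope="session")
def model():
    """Default synthetic beam model (shared; treat as read-only)."""
    return make_synthetic_model()


@pytest.fixture(scope="session")
def no_dip_model():
    return make_synthetic_model(SynthModelParams(tg_dip=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def cfg():
    return TransportConfig(seed=1)


def centered_pulse_oracle(s_prev, s_i, s_next, n_steps=2048):
    """Time-discretization oracle for the leaf-neighbour state fractions.

    Each leaf opens for an interval of its own open-time fraction
    centred at mid-projection; the four coefficients are the occupancy
    fractions of the neighbour states while the leaf of interest is
    open, counted on a midpoint time grid.
    """
    t = (np.arange(n_steps) + 0.5) / n_steps
    open_i = np.abs(t - 0.5) < s_i / 2
    open_p = np.abs(t - 0.5) < s_prev / 2
    open_n = np.abs(t - 0.5) < s_next / 2
    return np.array([
        np.mean(open_i & open_p & open_n),
        np.mean(open_i & ~open_p & ~open_n),
        np.mean(open_i & ~open_p & open_n),
        np.mean(open_i & open_p & ~open_n),
    ])
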