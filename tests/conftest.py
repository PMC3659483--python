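import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import ionfit

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def csan():
    """Two-current central-SAN model and its initial state."""
    return ionfit.io.minimal_cell("cSAN")


@pytest.fixture(scope="session")
def csan_trace(csan):
    """Two seconds of spontaneous cSAN activity with per-current traces."""
    params, x0 = csan
    return ionfit.simulate(
        params, x0, ionfit.StimulusProtocol.spontaneous(), 2.0, record_currents=True
    )


def make_one_current_model():
    """Small excitable single-current model used for cheap fitting tests."""
    from ionfit.model import (
        CurrentParameters,
        GateParameters,
        ModelParameters,
        RateParameters,
    )

    # fast-activating, slowly inactivating inward current plus leak:
    # quiescent at rest, fires one AP-like transient per stimulus
    p_gate = GateParameters(
        RateParameters(2000.0, -0.2, -40.0), RateParameters(100.0, 0.2, -40.0)
    )
    q_gate = GateParameters(
        RateParameters(20.0, 0.2, -60.0), RateParameters(80.0, -0.2, -60.0)
    )
    current = CurrentParameters(800.0, 40.0, p_gate, q_gate)
    params = ModelParameters((current,), gL=150.0, ErevL=-80.0)
    x0 = ionfit.CellState(Em=-80.0, gates=np.array([0.0, 0.8]))
    return params, x0


@pytest.fixture(scope="session")
def one_current_model():
    return make_one_current_model()
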