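import numpy as np
import pytest

from tvbopt import KuramotoParams, StimProtocol, burn_in, init_population

# Scaled trial protocol used throughout the closed-loop tests: 24 s steps
# (14 s resettle + 6 s baseline + 4 s stimulation).  Post-stimulation
# recovery of the population coherence takes ~15 s, so anything shorter
# contaminates the next trial's baseline.
SCALED_PROTOCOL = dict(step_duration_s=24.0, stim_window_s=4.0, baseline_window_s=6.0)


@pytest.fixture(scope="session")
def table1_params():
    """Reference population parameters (N=50, 8 Hz, gamma=0.8, I=30)."""
    return KuramotoParams()


@pytest.fixture(scope="session")
def scaled_protocol():
    return StimProtocol(**SCALED_PROTOCOL)


@pytest.fixture(scope="session")
def settled_state(table1_params):
    """A population burned in for 200 s (seed 0), shared read-only."""
    return burn_in(init_population(table1_params, 0), table1_params, 200.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
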