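import numpy as np
import pytest

from hypnoscore.hrv import RRWindow
from hypnoscore.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six short subject-nights shared by the cheaper integration tests."""
    params = SimulationParams(n_subjects=6, n_epochs=120, seed=101)
    return simulate_cohort(params)


def make_window(rr_ms, window_len=300.0):
    """Wrap raw interval values into an RRWindow with cumulative beat times."""
    rr = np.asarray(rr_ms, dtype=float)
    bt = np.cumsum(rr) / 1000.0
    return RRWindow(rr, bt, float(bt[-1]), window_len)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
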