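import numpy as np
import pytest

from nram.cell import resting_state
from nram.params import CellParams
from nram.protocols import pace_to_steady_state


@pytest.fixture(scope="session")
def params():
    return CellParams()


@pytest.fixture(scope="session")
def rest_single(params):
    return resting_state(params, "single_cell")


@pytest.fixture(scope="session")
def rest_constitutive(params):
    return resting_state(params, "constitutive")


@pytest.fixture(scope="session")
def paced_1hz(params):
    """12 beats at 1 Hz, single-cell mode; shared by metric tests."""
    return pace_to_steady_state(params, bcl=1000.0, n_beats=12,
                                mode="single_cell")


@pytest.fixture(scope="session")
def final_beat_metrics(paced_1hz):
    from nram.protocols import ap_metrics

    t0 = 11 * 1000.0
    beat = paced_1hz.window(t0, t0 + 1000.0)
    return ap_metrics(beat, stim_time=t0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
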