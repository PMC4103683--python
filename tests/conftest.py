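import numpy as np
import pytest

import spiculate as sp
from spiculate.io import PipelineConfig

DT = 0.05


@pytest.fixture(scope="session")
def spc_noiseless():
    """One noiseless SPC bout: insertion at 5 s, 45 s recording at 20 Hz."""
    preset = sp.make_preset("spc").with_(noise_sd=0.0)
    trace, events = sp.simulate_bout(preset, 5.0, 45.0, DT, seed=0)
    return preset, trace, events


@pytest.fixture(scope="session")
def spc_noiseless_result(spc_noiseless):
    preset, trace, events = spc_noiseless
    return preset, sp.BoutKinetics(trace, events, PipelineConfig()).fit()


@pytest.fixture
def flat_dff():
    """A flat %ΔF/F0 trace with an insertion event at 5 s."""
    from spiculate.datatypes import DffTrace, EventLog

    t = np.arange(0.0, 30.0, DT)
    return DffTrace(t, np.zeros_like(t), 1.0, EventLog({"insertion": [5.0]}))


def make_dff(values, dt=DT, insertion=None, f0=1.0):
    from spiculate.datatypes import DffTrace, EventLog

    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * dt
    events = EventLog({"insertion": [insertion]} if insertion is not None else {})
    return DffTrace(t, values, f0, events)
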