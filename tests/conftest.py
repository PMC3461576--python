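import numpy as np
import pytest

import tripsyn as ts


@pytest.fixture(scope="session")
def default_config():
    return ts.SynapseConfig(tail=400.0)


@pytest.fixture(scope="session")
def single_pulse_traces(default_config):
    """Single-release traces with and without astrocytic uptake (shared)."""
    on = ts.run_synapse(ts.single_pulse(), default_config)
    off = ts.run_synapse(ts.single_pulse(), default_config.without_uptake())
    return {"on": on, "off": off}


def nmdar_time_to_half_decay(trace):
    """Time (ms) from the NMDAR EPSC peak to half of it, interpolated."""
    i = trace["I_NMDA"]
    t = trace.t
    k = int(np.argmin(i))
    half = i[k] / 2
    seg, tt = i[k:], t[k:]
    j = int(np.where(seg >= half)[0][0])
    t_c = tt[j - 1] + (half - seg[j - 1]) / (seg[j] - seg[j - 1]) * (tt[j] - tt[j - 1])
    return float(t_c - t[k])


def normalized_ampar_decay(trace, window_ms=10.0):
    """(time-since-peak, |I_AMPA|/peak) over a window past the peak."""
    i = trace["I_AMPA"]
    k = int(np.argmin(i))
    n = int(window_ms / (trace.t[1] - trace.t[0]))
    return trace.t[k : k + n] - trace.t[k], i[k : k + n] / i[k]
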