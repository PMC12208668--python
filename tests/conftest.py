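import numpy as np
import pytest

from asetrace import NoiseModel, StimulusProtocol, default_template, simulate_trace


@pytest.fixture
def protocol():
    return StimulusProtocol()


@pytest.fixture
def noiseless_traces(protocol):
    """One noiseless trace per response class, with ground truth."""
    out = {}
    for label in ("ON", "OFF", "OFF2", "ON_OFF", "NONE"):
        raw, gt = simulate_trace(protocol, default_template(label), NoiseModel())
        out[label] = (raw, gt)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
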