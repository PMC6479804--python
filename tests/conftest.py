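import numpy as np
import pytest

from ldasg import SignalSeries, SyntheticECGSpec, generate_ecg


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def ecg_fixture():
    """10 s, 72 bpm, 360 Hz synthetic ECG with ground-truth R indices."""
    return generate_ecg(SyntheticECGSpec(seed=0))


@pytest.fixture
def ramp():
    return SignalSeries(0.3 * np.arange(200) - 7.0, 360.0)


@pytest.fixture
def constant():
    return SignalSeries(np.full(200, 2.5), 360.0)
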