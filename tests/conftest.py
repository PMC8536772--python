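import numpy as np
import pytest

from mmsgait.synthetic import GroundTruth, simulate_subject


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_recording():
    """One 3-node simulated walk shared across read-only tests."""
    truth = GroundTruth(seed=7)
    rec, realized = simulate_subject(truth, duration_s=180.0, rate_hz=100.0)
    return rec, realized
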