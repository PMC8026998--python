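import numpy as np
import pytest

from retinakit import synth


@pytest.fixture(scope="session")
def paper_protocol():
    """Standard protocol: 6 intensities x 20 reps, 350 ms flashes, 2 s dark."""
    return synth.make_protocol()


@pytest.fixture(scope="session")
def short_protocol():
    """Small single-intensity protocol for trace-tier tests."""
    return synth.make_protocol(intensities=[1e14], reps=5, flash_dur=0.35, dark_gap=0.7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
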