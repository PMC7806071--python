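import numpy as np
import pytest

from dyadsync import FeatureSequence, Transcript, Turn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_sequence():
    """10 frames at 10 ms over [0, 0.1) s, 4 dims."""
    rng = np.random.default_rng(0)
    return FeatureSequence(values=rng.normal(size=(10, 4)))


@pytest.fixture
def alternating_transcript():
    """A:[0,0.05) then B:[0.05,0.1)."""
    return Transcript(
        turns=[Turn("A", 0.0, 0.05, "hello there"), Turn("B", 0.05, 0.1, "hi friend")],
        session_id="toy",
    )


@pytest.fixture
def rank2_frames():
    """10 distinct 16-dim frames spanning a 2-dim subspace (AE capacity check)."""
    rng = np.random.default_rng(42)
    basis = rng.normal(size=(2, 16))
    coefs = rng.normal(size=(10, 2))
    return coefs @ basis
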