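import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aiia import RRRecord, generate_study, study1_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record(rng):
    """A 500-interval random-walk record with a label."""
    steps = rng.normal(0, 25, size=499)
    intervals = np.clip(800 + np.cumsum(np.r_[0.0, steps]), 300, 2200)
    return RRRecord("walk_000", intervals, label="HY")


@pytest.fixture(scope="session")
def tiny_corpus():
    """Five-class synthetic corpus at reduced length for fast CV tests."""
    return generate_study(study1_spec(300), seed=7)
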