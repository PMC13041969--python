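import numpy as np
import pytest
from hypothesis import settings

from neuromidi import EventStream, make_session_fixture

# deterministic property tests: same examples every run
settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_stream() -> EventStream:
    """Three labeled events, deliberately given out of time order."""
    return EventStream(labels=("A", "B", "A"), times=np.array([0.30, 0.25, 0.10]))


@pytest.fixture(scope="session")
def grooming_session(tmp_path_factory):
    """A full synthetic grooming session fixture written once per test run."""
    out = tmp_path_factory.mktemp("fixtures") / "grooming"
    return out, make_session_fixture(out, seed=11, scenario="grooming")


@pytest.fixture(scope="session")
def blink_session(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "blink"
    return out, make_session_fixture(out, seed=11, scenario="blink")
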