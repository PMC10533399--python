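import numpy as np
import pytest

from batcolony import tracking
from batcolony.synthetic import (
    SessionConfig,
    generate_group_session,
    make_matched_flightset,
)


@pytest.fixture(scope="session")
def session900():
    """A 15-minute five-bat session shared across test modules."""
    return generate_group_session(SessionConfig(n_bats=5, duration=900.0, seed=11))


@pytest.fixture(scope="session")
def matched_flights():
    """Two-bat session with 20 social and 20 non-social kinematically
    matched flights along one path."""
    return make_matched_flightset(20, 20, seed=5)


@pytest.fixture(scope="session")
def smoothed_track(session900):
    return tracking.smooth_positions(session900.tracks[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
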