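import numpy as np
import pytest

from dwellkit import (
    AcquisitionProtocol,
    KineticModel,
    render_movie,
    simulate_events,
)


@pytest.fixture(scope="session")
def protocol():
    """The standard 11-condition interval-imaging protocol."""
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_protocol():
    """Same schedule on a small camera field, for fast rendering tests."""
    return AcquisitionProtocol(field_shape=(128, 128))


@pytest.fixture(scope="session")
def rendered_fixture(small_protocol):
    """One rendered movie (tau_d = 0.2 s) with its ground-truth events.

    Default rendering parameters put the filtered spot response far above
    the detection threshold, so detection failures indicate algorithmic
    regressions rather than shot-noise bad luck.
    """
    truth = KineticModel.from_lifetimes(5.0, k_b=1.0)
    condition = 2
    events = simulate_events(truth, small_protocol, condition, 60, seed=42)
    movie = render_movie(events, small_protocol, condition, seed=7)
    return {"events": events, "movie": movie, "condition": condition, "model": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
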