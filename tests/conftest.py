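import numpy as np
import pytest

from scalphfo.simulate import (
    SimulationConfig,
    embed_events,
    generate_background,
    make_burst_event,
)


@pytest.fixture
def small_config():
    return SimulationConfig(
        duration_s=10.0, channel_labels=["C3", "C4"], rng_seed=1
    )


@pytest.fixture
def background(small_config):
    return generate_background(small_config)


@pytest.fixture
def recording_with_bursts(background, small_config):
    """Background with one ripple-band and one fast-ripple-band burst."""
    events = [
        make_burst_event("C3", 3000, 150.0, 80.0, 8, small_config.fs),
        make_burst_event("C4", 5000, 320.0, 80.0, 8, small_config.fs),
    ]
    rec, truths = embed_events(background, events)
    return rec, truths


@pytest.fixture
def rng():
    return np.random.default_rng(42)
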