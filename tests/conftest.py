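import numpy as np
import pytest

import striatumsim as ss


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_task():
    """2 stimuli / 2 channels, short trials for fast unit tests."""
    return ss.TaskConfig(
        n_channels=2,
        n_relevant_stimuli=2,
        n_distractors=0,
        trial_duration=400.0,
        exclusion_period=100.0,
        n_episodes=10,
        input_pop_size_per_stimulus=10,
        n_blocks=2,
    )


@pytest.fixture
def quiet_net():
    """Deterministic network: no background noise currents."""
    return ss.NetworkConfig(
        wiring=ss.ChannelWiring(n_d1=4, n_d2=4),
        noise_spn=0.0,
        noise_act=0.0,
    )
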