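import numpy as np
import pytest

from lithic_eeg import (
    EffectMap,
    Marker,
    Recording,
    SimulationConfig,
    load_montage,
    simulate_recording,
)


@pytest.fixture(scope="session")
def montage():
    return load_montage("builtin-32")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording(montage):
    """4-channel-equivalent toy: full montage, short noise recording."""
    gen = np.random.default_rng(0)
    data = gen.standard_normal((montage.n_channels, 1000))
    return Recording(
        data=data,
        rate=250.0,
        montage=montage,
        markers=[Marker("cut.hold", 100)],
        audio_cue=np.zeros(1000),
    )


@pytest.fixture(scope="session")
def fast_sim_config():
    """Reduced-scale simulation used by signal-chain tests: 250 Hz, few
    trials, artifacts off unless a test switches them on."""
    return SimulationConfig(
        rate=250.0,
        n_trials_per_task=4,
        blink_rate_per_min=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def clean_cut_recording(fast_sim_config):
    eff = EffectMap()
    return simulate_recording(
        fast_sim_config, eff, "S01", "cut",
        rng=np.random.default_rng(7), subject_factor=1.0,
    )
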