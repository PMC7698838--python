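import numpy as np
import pytest

from somnofuse.dataio import Recording, zscore_per_channel
from somnofuse.network import BackboneConfig, ModelConfig, SleepStageModel
from somnofuse.simulator import SimConfig, make_dataset

TINY_BLOCKS = ((3, 2, 4), (3, 1, 6))
SMALL_BLOCKS = ((5, 3, 8), (5, 3, 8), (3, 2, 16), (3, 1, 16), (3, 1, 32))


@pytest.fixture
def tiny_model():
    """3-channel model small enough for brute-force numeric checks."""
    cfg = ModelConfig(
        input_len=20,
        n_channels=3,
        backbone=BackboneConfig(blocks=TINY_BLOCKS),
        seed=1,
    )
    return SleepStageModel(cfg)


@pytest.fixture
def tiny_config():
    return ModelConfig(
        input_len=20,
        n_channels=3,
        backbone=BackboneConfig(blocks=TINY_BLOCKS),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_sim_config():
    return SimConfig(
        n_subjects=4,
        epochs_per_subject=60,
        sampling_rate=30.0,
        channels=("EEG", "EOG", "EMG"),
        channel_roles=("EEG", "EOG", "EMG"),
        noise_sigma=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_recordings(small_sim_config):
    """Four short synthetic recordings, z-scored, shared across tests."""
    cfg = small_sim_config
    return [
        zscore_per_channel(
            Recording(sid, epochs, hyp, cfg.channels, cfg.sampling_rate)
        )
        for sid, epochs, hyp in make_dataset(cfg)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
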