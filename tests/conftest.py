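import numpy as np
import pytest

from veinverify.synthgen import SynthConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Small dataset config: fast, but enough subjects/samples to split."""
    return SynthConfig(n_subjects=4, samples_per_subject=4, image_size=(32, 32),
                       n_vessels=3, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return make_dataset(tiny_config)


@pytest.fixture(scope="session")
def clean_config():
    """No jitter, no noise: every sample equals its subject template."""
    return SynthConfig(n_subjects=5, samples_per_subject=4, image_size=(32, 32),
                       n_vessels=3, noise_sd=0.0, jitter_shift=0.0,
                       jitter_rot=0.0, jitter_gain=0.0, seed=3)


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return make_dataset(clean_config)
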