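import numpy as np
import pytest
from hypothesis import settings

from pupilbias.config import SimConfig
from pupilbias.synthgen import generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A scaled-down study: 2 participants/group, 20 PV and 8 DPT trials."""
    return SimConfig(n_per_group=2, pv_trials=20, dpt_trials=8, seed=7,
                     blink_rate=0.05, artifact_rate=0.002)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
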