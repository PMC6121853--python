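import numpy as np
import pytest

from stripesignal import SyntheticConfig
from stripesignal.synth import gen_light_environment, gen_spectra_dataset, gen_visual_system


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(seed=12345)


@pytest.fixture(scope="session")
def visual_system(config):
    return gen_visual_system(config)


@pytest.fixture(scope="session")
def light_env(config):
    return gen_light_environment(config)


@pytest.fixture(scope="session")
def patch_dataset(config):
    """Dominant + subordinate facial patch spectra for the default fish count."""
    return gen_spectra_dataset(config)


@pytest.fixture(scope="session")
def contrast_records(patch_dataset, visual_system, light_env):
    """Pairwise patch contrasts for the default synthetic dataset."""
    from stripesignal import DEFAULT_ADJACENCY, pairwise_contrasts

    return pairwise_contrasts(patch_dataset, DEFAULT_ADJACENCY, visual_system, light_env)


@pytest.fixture
def rng():
    return np.random.default_rng(98765)
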