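import numpy as np
import pytest

from memcolour import GeneratorConfig, default_stimuli, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """5 observers x 3 stimuli x 3 repeats, deterministic."""
    config = GeneratorConfig(
        stimuli=default_stimuli()[:3], n_observers=5, n_repeats=3, seed=99
    )
    data, truth = generate_dataset(config)
    return config, data, truth


@pytest.fixture(scope="session")
def closure_dataset():
    """Model-conforming, response-noise-free dataset at a full design."""
    config = GeneratorConfig(
        stimuli=default_stimuli(), n_observers=20, n_repeats=5,
        response_noise_sd=0.0, seed=7,
    )
    data, truth = generate_dataset(config)
    return config, data, truth
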