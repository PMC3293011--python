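import dataclasses

import numpy as np
import pytest

from ecgtriage import SynthConfig, TrainConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free generator settings for ground-truth comparisons."""
    return SynthConfig(n_cases=40, stemi_prevalence=0.4, noise_sd=0.0,
                       baseline_wander=(0.0, 0.33), amplitude_jitter_sd=0.05,
                       heart_rate_jitter_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return generate_cohort(clean_config)


@pytest.fixture(scope="session")
def default_cohort():
    """A small cohort under the default (noisy) study-like conditions."""
    return generate_cohort(dataclasses.replace(SynthConfig(), n_cases=30, seed=5))


@pytest.fixture
def fast_train_config():
    """Reduced epochs/members for unit-level ensemble tests."""
    return TrainConfig(n_epochs=150, n_members=5, learning_rate=0.5, seed=0)


@pytest.fixture
def toy_separable():
    """Two linearly separable 20-d clusters, n=200."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(200, 20))
    t = (rng.random(200) < 0.5).astype(float)
    X[t == 1, :3] += 2.5
    X[t == 0, :3] -= 2.5
    return X, t
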