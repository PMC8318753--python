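import numpy as np
import pytest

from svml.phantom import PhantomSpec, generate_lung_phantom
from svml.pipeline import PipelineConfig, fit


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(noise_sigma=0.0, seed=0)
    image, mask = generate_lung_phantom(spec)
    return spec, image, mask


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(seed=0)  # default noise_sigma = 10
    image, mask = generate_lung_phantom(spec)
    return spec, image, mask


@pytest.fixture(scope="session")
def training_pairs():
    return [generate_lung_phantom(PhantomSpec(seed=s)) for s in range(3)]


@pytest.fixture(scope="session")
def trained_model(training_pairs):
    """Self-paced model trained on three default-noise phantoms."""
    config = PipelineConfig()
    model, state = fit(
        [img for img, _ in training_pairs],
        [msk for _, msk in training_pairs],
        config,
    )
    return model, state, config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
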