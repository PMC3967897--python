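import numpy as np
import pytest

from leafspec import GeneratorConfig, generate
from leafspec.synthetic import AbsorptionFeature


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic dataset under the default study conditions (35 plants)."""
    return generate(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def single_feature_config():
    """One pigment feature only: exactly one spectrally active constituent."""
    return GeneratorConfig(
        n_plants=35,
        features=(AbsorptionFeature(680.0, 40.0, 0.035, "pigment"),),
        coupling_rho=1.0,
        noise_sd=0.005,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
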