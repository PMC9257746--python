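import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def synthetic_screen():
    """A default-condition synthetic screen (seed 1)."""
    from coamscreen import SyntheticConfig, generate_training_screen

    return generate_training_screen(SyntheticConfig(seed=1))


@pytest.fixture
def fitted_model(synthetic_screen):
    from coamscreen import feature_matrix, nipals_fit

    X = feature_matrix(synthetic_screen)
    return nipals_fit(X, synthetic_screen.experimental_labels())
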