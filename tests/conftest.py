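import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_planted():
    """Small planted-band dataset shared by fast selector/model tests."""
    from specswarm import small_planted_problem

    return small_planted_problem(n_samples=60, n_wavelengths=12, seed=3)


@pytest.fixture(scope="session")
def fast_selector_cfg():
    from specswarm import SelectorConfig

    return SelectorConfig(
        pop_size=8,
        max_iter=5,
        seed=7,
        fitness_n_estimators=15,
        fitness_learning_rate=0.3,
        fitness_max_bin=16,
    )
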