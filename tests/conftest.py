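import pytest
from hypothesis import HealthCheck, settings

from avoidrl import ModelParameters, TaskConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    """The published protocol: 12 sessions x 25 trials, 12-s steps."""
    return TaskConfig()


@pytest.fixture(scope="session")
def small_config() -> TaskConfig:
    """A desk-scale protocol for fast tests; shock schedule unchanged."""
    return TaskConfig(n_sessions=2, trials_per_session=5, homecage_steps=40)


@pytest.fixture(scope="session")
def center_params() -> ModelParameters:
    """Defaults = center points of the default search grid."""
    return ModelParameters()
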