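import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neutralquery import FeedbackParams, SwitchRule, load_fixtures

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixtures():
    """Embedded published counts."""
    return load_fixtures()


@pytest.fixture(scope="session")
def empirical_params():
    """Feedback probabilities at the coded-corpus point estimates
    (rounded rates 0.92 / 0.65 used throughout worked examples)."""
    return FeedbackParams(alpha_c=0.92, beta_i=0.65)


@pytest.fixture
def matching_rule():
    return SwitchRule(kind="probability_matching")


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
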