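import numpy as np
import pytest

from foragerow.simulate import AgentConfig, TaskConfig, generate_cohort, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_session():
    """One full session of the default (noisy, deliberating) agent."""
    return generate_session(AgentConfig(), TaskConfig(), seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Five short sessions with ground-truth agents attached."""
    return generate_cohort(5, seed=7, task=TaskConfig(max_offers=24))
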