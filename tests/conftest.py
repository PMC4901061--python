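import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mugrm as mg

mg.TestDesign.__test__ = False  # domain class, not a test case

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """One small dataset (N=300, K=4, C=3, rho=0.5) shared by sampler tests."""
    cond = mg.StudyCondition(300, 4, 0.5, seed=7)
    return mg.generate_dataset(cond, 0)


@pytest.fixture(scope="session")
def medium_bundle():
    """A study-sized dataset (N=500, K=20, rho=0.2)."""
    cond = mg.StudyCondition(500, 20, 0.2, seed=11)
    return mg.generate_dataset(cond, 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
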