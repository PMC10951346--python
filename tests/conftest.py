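import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tgckit.cognition import score_cohort
from tgckit.synthetic import CohortSpec, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort():
    """Default stated-world cohort: 78 controls, 128 MCI, 83 MCI+rMDD."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def scored(cohort):
    return score_cohort(cohort)


@pytest.fixture(scope="session")
def patients(scored):
    return scored[scored["group"] != "control"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240319)
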