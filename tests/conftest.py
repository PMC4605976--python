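import numpy as np
import pytest
from hypothesis import settings

from metabopls import SyntheticSpec, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """Default 18 COPD / 28 OSAS cohort with the three standard blocks."""
    return generate_cohort(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def planted_cohort():
    """Balanced 60/60 cohort with five serum variables shifted by 1.5 SD."""
    planted = {f"serum__v{i}": 1.5 for i in range(1, 6)}
    return generate_cohort(
        SyntheticSpec(n_group_a=60, n_group_b=60, planted=planted, seed=11)
    ), set(planted)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
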