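import numpy as np
import pytest

from caratrial import PatientData, get_scenario, response_probability


def simulate_dataset(scenario, n, seed, arm_prob=0.5):
    """Balanced two-arm dataset drawn from a scenario's true model."""
    rng = np.random.default_rng(seed)
    x = (rng.random((n, scenario.params.d)) < scenario.covariate_dist).astype(np.int64)
    arm = (rng.random(n) < arm_prob).astype(np.int64)
    p = response_probability(scenario.params, arm, x)
    y = (rng.random(n) < p).astype(np.int64)
    return PatientData(x=x, arm=arm, y=y, cohort=np.ones(n, dtype=np.int64))


@pytest.fixture(scope="session")
def sc1():
    return get_scenario(1)


@pytest.fixture(scope="session")
def sc10():
    return get_scenario(10)


@pytest.fixture(scope="session")
def sc19():
    return get_scenario(19)
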