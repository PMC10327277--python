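import numpy as np
import pytest

from lifegap.agegrid import AgeGrid, default_grid
from lifegap.cause_classification import default_cause_map, group_dataset
from lifegap.synthetic import demo_scenario, generate


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def two_group_grid():
    """[0, 5) plus open 5+ — small enough to recurse by hand."""
    return AgeGrid((0.0, 5.0))


@pytest.fixture(scope="session")
def two_group_rates():
    """m = 0.02 on [0,5) (with a = 2.5) and 0.1 on 5+; hand recursion
    gives q0 = 0.095238..., e0 = 13.809524, e-dagger = 10.181406."""
    return np.array([0.02, 0.1])


@pytest.fixture(scope="session")
def demo_dataset_exact():
    """Noise-free demo dataset: rates reproduce the scenario exactly."""
    return generate(demo_scenario(noise="none"))


@pytest.fixture(scope="session")
def demo_dataset_poisson():
    return generate(demo_scenario(seed=12345, noise="poisson"))


@pytest.fixture(scope="session")
def grouped_demo_exact(demo_dataset_exact):
    return group_dataset(demo_dataset_exact, default_cause_map())
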