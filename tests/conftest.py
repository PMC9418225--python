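import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_problem():
    from vasotherm.fixtures import make_three_layer_toy

    return make_three_layer_toy(12, 12, 2)


@pytest.fixture(scope="session")
def toy_result(toy_problem):
    from vasotherm.pipeline import solve_problem

    return solve_problem(toy_problem, method="dense")


@pytest.fixture(scope="session")
def chain_problem():
    from vasotherm.fixtures import make_vessel_voxel_chain

    return make_vessel_voxel_chain()


@pytest.fixture(scope="session")
def chain_result(chain_problem):
    from vasotherm.pipeline import solve_problem

    return solve_problem(chain_problem, method="dense")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
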