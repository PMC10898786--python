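import numpy as np
import pytest

from hiddensingle.cohort import sample_categories, sample_path
from hiddensingle.aggregate import ResponseSequence
from hiddensingle.design import assign_training_features
from hiddensingle.strategy import AggregateParams, non_solver_params, solver_params


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def solver():
    return solver_params()


@pytest.fixture(scope="session")
def non_solver():
    return non_solver_params()


@pytest.fixture(scope="session")
def solver_cohort():
    """120 sequences simulated from the bundled solver parameters."""
    params = solver_params()
    gen = np.random.default_rng(555)
    cohort = []
    for i in range(120):
        path = sample_path(params, 25, gen)
        cohort.append(ResponseSequence(f"p{i:03d}", sample_categories(path, params, gen)))
    return cohort


@pytest.fixture
def features(rng):
    return assign_training_features(rng)


def random_valid_params(gen: np.random.Generator) -> AggregateParams:
    """Random parameters respecting all structural constraints."""
    a = gen.dirichlet(np.ones(4))
    X = np.zeros((4, 4))
    for i in range(3):
        X[i, i:] = gen.dirichlet(np.ones(4 - i))
    X[3, 3] = 1.0
    W = np.zeros((4, 4))
    W[0, 0] = 1.0
    for i in range(1, 4):
        W[i, : i + 1] = gen.dirichlet(np.ones(i + 1))
    return AggregateParams(a=a, X=X, W=W)
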