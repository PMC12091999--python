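import numpy as np
import pytest

import kinresp as kr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_minimal():
    """One fixed small cofactor model with a certified attractor."""
    model = kr.build_minimal_model(12, 18, 0.75, 10.0, np.random.default_rng(42))
    st = kr.find_attractor(model, [model.default_initial()])
    return model, st


@pytest.fixture(scope="session")
def small_catalytic():
    model = kr.build_catalytic_variant(12, 16, 20.0, np.random.default_rng(43))
    st = kr.find_attractor(model, [model.default_initial()])
    return model, st


class LinearModel:
    """Minimal model-contract object: dx/dt = A (x - x_fix)."""

    requires_positive = False

    def __init__(self, A, x_fix):
        self.A = np.asarray(A, dtype=float)
        self.x_fix = np.asarray(x_fix, dtype=float)
        self.n_state = len(self.x_fix)

    def rhs(self, x):
        return self.A @ (x - self.x_fix)

    def jac(self, x):
        return self.A

    def default_initial(self):
        return np.ones(self.n_state)


@pytest.fixture
def linear_model_factory():
    return LinearModel
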