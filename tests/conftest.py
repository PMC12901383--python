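import numpy as np
import pytest

from opso.problems import BoundedProblem


@pytest.fixture
def sphere5():
    """Sphere on [-5, 5]^10 (the convergence-test box)."""

    def batch(X):
        X = np.atleast_2d(np.asarray(X, float))
        return np.sum(X * X, axis=1)

    return BoundedProblem(
        dimension=10,
        lower=np.full(10, -5.0),
        upper=np.full(10, 5.0),
        objective=lambda x: float(np.sum(np.asarray(x) ** 2)),
        name="sphere5",
        batch_objective=batch,
    )


@pytest.fixture
def unit_problem():
    """1-D problem on [0, 1]."""
    return BoundedProblem(
        dimension=1,
        lower=np.array([0.0]),
        upper=np.array([1.0]),
        objective=lambda x: float(x[0] ** 2),
        name="unit",
    )
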