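import numpy as np
import pytest

from mcoin.models import MotifModel
from mcoin.synthetic import DatasetSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_model():
    """Uninformative motif: uniform PWM over a uniform background."""
    return MotifModel(
        theta1=np.full((4, 4), 0.25), theta0=np.full(4, 0.25), lam=0.5
    )


@pytest.fixture
def conserved_model():
    """Nearly deterministic width-4 PWM (consensus ACGT) on uniform background."""
    eps = 0.001
    theta1 = np.full((4, 4), eps)
    for j in range(4):
        theta1[j, j] = 1.0 - 3 * eps
    return MotifModel(theta1=theta1, theta0=np.full(4, 0.25), lam=0.01)


@pytest.fixture
def perfect_dataset():
    """Fully conserved planted dataset (every occurrence equals the consensus)."""
    return generate_dataset(DatasetSpec(target_ic=2.0, seed=99))


@pytest.fixture
def weak_dataset():
    return generate_dataset(DatasetSpec(target_ic=1.08, seed=42))


def _random_pwm(rng, width):
    theta = rng.dirichlet(np.ones(4), size=width)
    return np.clip(theta, 1e-9, None) / np.clip(theta, 1e-9, None).sum(
        axis=1, keepdims=True
    )


@pytest.fixture
def random_pwm():
    """Factory for strictly positive random PWMs."""
    return _random_pwm
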