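import numpy as np
import pytest

from pretextnet import phantom
from pretextnet.core_io import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.random((32, 32)))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small split cohort at 32x32 used by training smoke tests."""
    cohort = phantom.generate_cohort(n=24, prevalence=0.5, seed=7, size=(32, 32))
    return phantom.patient_split(cohort, seed=7)


def finite_difference_grad(fn, x, eps=1e-3):
    """Central-difference gradient of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        grad[idx] = (fn(xp) - fn(xm)) / (2 * eps)
        it.iternext()
    return grad
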