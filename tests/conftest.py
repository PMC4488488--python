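import numpy as np
import pytest

from tledlite import make_box_mesh


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(params=["T4", "T4ANP", "H8"])
def element_type(request):
    return request.param


@pytest.fixture
def small_box(element_type):
    """A 1x1x2-cell unit-ish box of each element type."""
    return make_box_mesh(1, 1, 2, 1.0, 1.0, 2.0, element_type)


def random_spd_C(rng, n=1, scale=0.3):
    """Random admissible right Cauchy-Green tensors C = F^T F, det F > 0."""
    F = np.eye(3) + scale * rng.standard_normal((n, 3, 3))
    # reflip any inverted F
    neg = np.linalg.det(F) <= 0.05
    F[neg] = np.eye(3) + 0.1 * rng.standard_normal((int(neg.sum()), 3, 3))
    return np.einsum("nab,nac->nbc", F, F)
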