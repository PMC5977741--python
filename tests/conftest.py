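import numpy as np
import pytest

from tensormda.core import TensorDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_ds(rng):
    """20 random 6x7 trials, two balanced classes, weak random signal."""
    X = rng.standard_normal((20, 6, 7))
    y = np.repeat([0, 1], 10)
    X[y == 1] += 0.3 * rng.standard_normal((6, 7))
    return TensorDataset(X, y)


@pytest.fixture
def toy_ds(rng):
    """12 random 3x4 trials (J1*J2 = 12), for brute-force vectorised oracles."""
    X = rng.standard_normal((12, 3, 4))
    y = np.repeat([0, 1], 6)
    X[y == 1] += 0.5
    return TensorDataset(X, y)


def make_isotropic_rank1_ds(j1=5, j2=6, delta=0.3, i=1, j=2):
    """Two classes with means +/- e_i e_j', within-deviations running over all
    +/- delta*E_kl basis matrices, so the within-scatter is exactly isotropic
    and the unique discriminant direction is exactly e_i (x) e_j."""
    u = np.zeros(j1)
    u[i] = 1.0
    v = np.zeros(j2)
    v[j] = 1.0
    X, y = [], []
    for c, s in ((0, -1), (1, 1)):
        for a in range(j1):
            for b in range(j2):
                E = np.zeros((j1, j2))
                E[a, b] = delta
                X.append(s * np.outer(u, v) + E)
                y.append(c)
                X.append(s * np.outer(u, v) - E)
                y.append(c)
    return TensorDataset(np.array(X), np.array(y)), u, v


def random_stiefel(rng, rows, cols):
    Q, R = np.linalg.qr(rng.standard_normal((rows, cols)))
    return Q * np.sign(np.where(np.diag(R) == 0, 1.0, np.diag(R)))
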