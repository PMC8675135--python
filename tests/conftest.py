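import numpy as np
import pytest

from mpssi.core_mps import DenseState, mps_from_dense
from mpssi.oracle import dense_number, dense_sz


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dense_state(rng, L, complex_=False):
    v = rng.standard_normal(4**L)
    if complex_:
        v = v + 1j * rng.standard_normal(4**L)
    v /= np.linalg.norm(v)
    return DenseState(v, L)


def random_sector_state(rng, L, n_elec, sz=None):
    """Random normalized state restricted to one (N, Sz) sector."""
    n = dense_number(L).diagonal()
    if sz is None:
        mask = n == n_elec
    else:
        z = dense_sz(L).diagonal()
        mask = (n == n_elec) & (np.abs(z - sz) < 1e-12)
    v = np.zeros(4**L)
    idx = np.nonzero(mask)[0]
    v[idx] = rng.standard_normal(idx.size)
    v /= np.linalg.norm(v)
    return DenseState(v, L)


def as_mps(state, tol=0.0):
    return mps_from_dense(state, tol)
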