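import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from afpdomains import DomainMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(X, labels, row_prefix="P", col_prefix="IPR"):
    """Wrap a dense 0/1 array into a DomainMatrix with generated ids."""
    X = np.asarray(X, dtype=np.int8)
    n, m = X.shape
    return DomainMatrix(
        sp.csr_matrix(X),
        row_ids=[f"{row_prefix}{i:03d}" for i in range(n)],
        col_ids=[f"{col_prefix}{j:06d}" for j in range(m)],
        labels=np.asarray(labels, dtype=np.int64),
    )


def random_binary_matrix(rng, n, m, density=0.3, pos_frac=0.3):
    """A random binary DomainMatrix with no all-zero rows and both classes."""
    X = (rng.random((n, m)) < density).astype(np.int8)
    for i in np.flatnonzero(X.sum(axis=1) == 0):
        X[i, rng.integers(m)] = 1
    labels = np.where(rng.random(n) < pos_frac, 1, 2)
    if len(np.unique(labels)) < 2:
        labels[0] = 1
        labels[-1] = 2
    return make_matrix(X, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
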