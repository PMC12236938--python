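import numpy as np
import pytest

from profet.grn import GRNModel
from profet.preprocess import SnapshotSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_gene_model():
    """Gene 1 inhibits gene 0; noise off by default."""
    J = np.array([[0, -1], [0, 0]])
    lam = np.ones((2, 2))
    lam[0, 1] = 0.2
    theta = np.ones((2, 2))
    theta[0, 1] = 2.0
    n = np.ones((2, 2))
    n[0, 1] = 4
    return GRNModel(J=J, g=np.array([2.0, 1.0]), k=np.array([1.0, 0.5]),
                    lam=lam, theta=theta, n=n, D=0.0)


@pytest.fixture
def unregulated_model():
    J = np.zeros((3, 3), dtype=int)
    ones = np.ones((3, 3))
    return GRNModel(J=J, g=np.array([1.0, 4.0, 9.0]), k=np.array([0.5, 1.0, 3.0]),
                    lam=ones, theta=ones, n=ones, D=0.0)


@pytest.fixture
def small_series(rng):
    """Three 30-cell snapshots over 5 genes with drifting means."""
    mats = [np.abs(rng.normal(loc=mu, scale=1.0, size=(30, 5))) for mu in (1.0, 2.0, 3.0)]
    return SnapshotSeries(times=[0.0, 1.0, 2.0], matrices=mats,
                          gene_names=[f"G{i}" for i in range(5)])
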