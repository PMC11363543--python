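import numpy as np
import pytest

from thcdea.dea_sbm import DeaProblem
from thcdea.panel_io import PROVINCES_29, load_fixture
from thcdea.spatial_autocorr import build_weights, rook29_weights


@pytest.fixture(scope="session")
def rook29():
    return rook29_weights()


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_efficiency").values


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_malmquist").values


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4_moran").values


@pytest.fixture
def abc_problem():
    """Three units on one input / one output: A=(2,2), B=(4,4), C=(4,2).

    A and B span the VRS frontier; C is dominated by A.
    """
    X = np.array([[2.0, 4.0, 4.0]])
    Y = np.array([[2.0, 4.0, 2.0]])
    return X, Y


@pytest.fixture
def ring4():
    labels = ["a", "b", "c", "d"]
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
    return build_weights(edges, labels)


def random_dea_problem(rng, n=None, m=None, s=None):
    """Small strictly positive DEA instance for property tests."""
    n = n or rng.integers(2, 5)
    m = m or rng.integers(1, 3)
    s = s or rng.integers(1, 3)
    X = rng.uniform(1.0, 10.0, size=(m, n))
    Y = rng.uniform(1.0, 10.0, size=(s, n))
    return X, Y
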