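import numpy as np
import pytest

from tsdea import DMUPanel


def make_panel(X, Y, Z=None, groups=None):
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    return DMUPanel(
        dmu_id=np.array([chr(ord("A") + i) for i in range(n)], dtype=object),
        group=np.asarray(groups if groups is not None else ["g"] * n,
                         dtype=object),
        X=X,
        Y=np.atleast_2d(np.asarray(Y, float)),
        Z=None if Z is None else np.atleast_2d(np.asarray(Z, float)),
    )


def random_panel(rng, n=None, K=None, M=None):
    """Small random positive panel for property tests."""
    n = n or int(rng.integers(3, 16))
    K = K or int(rng.integers(1, 4))
    M = M or int(rng.integers(1, 3))
    X = rng.uniform(0.5, 10.0, (n, K))
    Y = rng.uniform(0.5, 10.0, (n, M))
    return make_panel(X, Y)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_crs_panel():
    # single input/output; efficiency is the productivity ratio y/x
    # divided by its maximum: A 1.0, B 0.5, C 0.2
    return make_panel([[2], [4], [5]], [[2], [2], [1]])


@pytest.fixture
def weak_efficiency_panel():
    # D matches B's output with 4 extra units of input 1: theta_D = 1
    # but with a positive slack (weak efficiency)
    return make_panel([[2, 4], [4, 2], [8, 2]], [[1], [1], [1]])
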