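import numpy as np
import pytest

from commutefc import laplacian, validate_connectome


def random_connected_connectome(n, seed, density=0.4, integer=True):
    """Random connected weighted graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    for attempt in range(200):
        w = np.where(rng.random((n, n)) < density,
                     np.ceil(rng.lognormal(1.0, 1.0, (n, n))), 0.0)
        w = np.triu(w, 1)
        w = w + w.T
        if not integer:
            w = w * rng.uniform(0.5, 1.5)
            w = np.triu(w, 1)
            w = w + w.T
        try:
            c = validate_connectome(w)
            laplacian(c)  # raises if disconnected
            return c
        except ValueError:
            continue
    raise RuntimeError("could not draw a connected graph")


@pytest.fixture
def make_connectome():
    return random_connected_connectome


@pytest.fixture
def edge():
    """Single weighted edge: the smallest valid connectome."""
    return validate_connectome([[0.0, 3.0], [3.0, 0.0]])


@pytest.fixture
def path3():
    """Unit-weight path graph 0–1–2."""
    return validate_connectome([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.fixture
def triangle():
    """Unit-weight K3."""
    return validate_connectome(np.ones((3, 3)) - np.eye(3))
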