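import numpy as np
import pytest
from hypothesis import settings

import selfsim as ss

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def k3():
    return ss.Graph.from_edges("abc", [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return ss.Graph.from_edges("abc", [("a", "b"), ("b", "c")])


@pytest.fixture
def star4():
    return ss.Graph.from_edges("hxyz", [("h", "x"), ("h", "y"), ("h", "z")])


@pytest.fixture(scope="session")
def gasket5():
    return ss.sierpinski_gasket(5)


@pytest.fixture(scope="session")
def gasket5_spectrum(gasket5):
    return ss.spectrum(ss.laplacian(gasket5))


def random_graph_cases(n_cases=30, n_lo=5, n_hi=40, seed=0):
    """Connected random test graphs of varied size and density."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_cases:
        n = int(rng.integers(n_lo, n_hi))
        p = float(rng.uniform(0.15, 0.7))
        g = ss.random_gnp(n, p, int(rng.integers(2**31)))
        try:
            gc = ss.giant_component(g)
        except ss.GraphError:
            continue
        if gc.n >= 3:
            out.append(gc)
    return out
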