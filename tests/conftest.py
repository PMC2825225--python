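import numpy as np
import pytest

from netgrid.network import Network
from netgrid.synth import SynthSpec, generate


@pytest.fixture
def triangle() -> Network:
    return Network(["a", "b", "c"], {("a", "b"), ("b", "c"), ("a", "c")})


@pytest.fixture
def path4() -> Network:
    return Network(["a", "b", "c", "d"], {("a", "b"), ("b", "c"), ("c", "d")})


@pytest.fixture
def two_components() -> Network:
    return Network(["a", "b", "c", "d"], {("a", "b"), ("c", "d")})


@pytest.fixture
def modular_small() -> Network:
    """Deterministic 2-module planted-partition network, ~30 nodes."""
    return generate(SynthSpec(module_sizes=(15, 15), p_in=0.4, p_out=0.05, seed=7))


def random_instance(rng: np.random.Generator, n: int):
    """Random weight matrix + valid random layout on a grid with slack."""
    from netgrid.optimize import init_random, make_grid

    W = rng.integers(-5, 10, size=(n, n))
    W = W + W.T
    np.fill_diagonal(W, 0)
    width, height = make_grid(n, 0.25)
    coords = init_random(n, width, height, rng)
    return W, coords, width, height
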