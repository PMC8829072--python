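import numpy as np
import pytest

from isvor import AbmConfig, Graph, IsvorParams


def params_with(**rates) -> IsvorParams:
    """IsvorParams with every probability zero except the given ones."""
    zero = {f: 0.0 for f in IsvorParams().probability_fields}
    k = rates.pop("k", 10.0)
    return IsvorParams(**{**zero, **rates}, k=k)


@pytest.fixture
def defaults() -> IsvorParams:
    return IsvorParams()


@pytest.fixture
def edge_graph() -> Graph:
    """Two nodes joined by one edge."""
    return Graph(2, np.array([[0, 1]]))


@pytest.fixture
def path3() -> Graph:
    """Path 0-1-2."""
    return Graph(3, np.array([[0, 1], [1, 2]]))


@pytest.fixture
def isolated() -> Graph:
    """A single node with no edges."""
    return Graph(1, np.empty((0, 2), dtype=np.int64))


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    """n points uniformly distributed on the 5-dimensional unit simplex."""
    x = rng.dirichlet(np.ones(5), size=n)
    return x
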