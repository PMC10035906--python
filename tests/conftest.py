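import numpy as np
import pytest

from spatnetviz import SpatialNetwork
from spatnetviz import fixtures as fx


@pytest.fixture
def rng():
    return np.random.default_rng(20230323)


@pytest.fixture
def path_graph_net():
    """3-node path graph on a line: 0 - 1 - 2."""
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 2.0
    return SpatialNetwork(coords, w, ["a", "b", "c"])


@pytest.fixture
def star_net():
    """Star: center node 0 with 5 leaves on a circle."""
    ang = np.linspace(0, 2 * np.pi, 5, endpoint=False)
    coords = np.vstack([[0, 0, 0], np.column_stack([np.cos(ang), np.zeros(5), np.sin(ang)])])
    w = np.zeros((6, 6))
    for leaf in range(1, 6):
        w[0, leaf] = w[leaf, 0] = float(leaf)
    return SpatialNetwork(coords, w)


@pytest.fixture
def geometric_net():
    return fx.random_geometric_network(20, 0.6, seed=11)


def random_networks(count, seed, n_range=(3, 25)):
    """Yield `count` random geometric networks with at least one link."""
    rng = np.random.default_rng(seed)
    made = 0
    while made < count:
        n = int(rng.integers(*n_range))
        net = fx.random_geometric_network(n, float(rng.uniform(0.4, 1.2)), seed=int(rng.integers(2**31)))
        if net.n_links > 0:
            made += 1
            yield net
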