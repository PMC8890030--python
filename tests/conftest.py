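import numpy as np
import pytest

from richconn.richclub import BinaryGraph


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


def random_graph(n: int, p: float, rng: np.random.Generator) -> BinaryGraph:
    """Erdos-Renyi G(n, p) as a BinaryGraph."""
    iu, ju = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=np.int8)
    on = rng.random(len(iu)) < p
    adj[iu[on], ju[on]] = 1
    adj |= adj.T
    return BinaryGraph(adj)


@pytest.fixture(scope="session")
def toy_core_graph():
    """8 nodes: a 3-clique core (0,1,2) with feeders and pendant nodes."""
    edges = [(0, 1), (0, 2), (1, 2),          # core triangle
             (0, 3), (1, 4), (2, 5),          # feeders
             (3, 4),                          # one local edge
             (5, 6), (6, 7)]                  # pendant chain
    adj = np.zeros((8, 8), dtype=np.int8)
    for a, b in edges:
        adj[a, b] = adj[b, a] = 1
    return BinaryGraph(adj)
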