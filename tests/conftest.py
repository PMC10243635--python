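"""Shared fixtures: small closed-form graphs and seeded random graph factories."""

import numpy as np
import pytest

from diffwalk import UndirectedGraph


@pytest.fixture
def triangle():
    return UndirectedGraph.from_edges([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def p4():
    """Path graph 0-1-2-3 (bipartite; walk spectrum cos(k*pi/3))."""
    return UndirectedGraph.from_edges([(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def k4():
    return UndirectedGraph.from_edges(
        [(i, j) for i in range(4) for j in range(i + 1, 4)]
    )


@pytest.fixture
def lollipop():
    """Triangle 0-1-2 with pendant edge 2-3; stationary (1/4, 1/4, 3/8, 1/8)."""
    return UndirectedGraph.from_edges([(0, 1), (1, 2), (0, 2), (2, 3)])


@pytest.fixture
def dumbbell():
    """Two triangles joined by a bridge edge 2-3."""
    return UndirectedGraph.from_edges(
        [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
    )


def random_connected_graph(n: int, mean_degree: float, seed: int) -> UndirectedGraph:
    """Erdos-Renyi G(n, p) conditioned on connectivity (retries the seed)."""
    from scipy.sparse.csgraph import connected_components

    p = mean_degree / (n - 1)
    rng = np.random.default_rng(seed)
    for _ in range(200):
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < p
        g = UndirectedGraph.from_edges(
            np.column_stack([iu[mask], ju[mask]]), n_nodes=n
        )
        if g.n_edges and connected_components(g.adjacency(), directed=False)[0] == 1:
            return g
    raise RuntimeError("could not draw a connected graph")


@pytest.fixture
def random_graph_factory():
    return random_connected_graph
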