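"""Shared fixtures: small graphs with known structure."""

import networkx as nx
import numpy as np
import pytest

from netgene.graph import Graph


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])


@pytest.fixture
def path4() -> Graph:
    """Path a - b - c - d."""
    return Graph.from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])


@pytest.fixture
def two_cliques() -> Graph:
    """Two disjoint 10-cliques; the canonical guilt-by-association fixture."""
    edges = []
    for block, offset in (("A", 0), ("B", 10)):
        for i in range(10):
            for j in range(i + 1, 10):
                edges.append((f"{block}{offset + i}", f"{block}{offset + j}", 1.0))
    return Graph.from_edges(edges)


def random_graph(n: int, p: float, seed: int, weighted: bool = False) -> Graph:
    """Connected-ish Erdos-Renyi graph as a netgene Graph."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    rng = np.random.default_rng(seed)
    edges = [
        (f"n{u}", f"n{v}", float(rng.uniform(0.5, 2.0)) if weighted else 1.0)
        for u, v in g.edges()
    ]
    names = [f"n{i}" for i in range(n)]
    return Graph.from_edges(edges, nodes=names)


@pytest.fixture
def rand30() -> Graph:
    return random_graph(30, 0.2, seed=7)
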