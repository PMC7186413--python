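"""Graph data model for protein-protein interaction networks.

Nodes are opaque gene identifiers (strings) mapped to stable integer
indices in order of first appearance.  The adjacency structure is
undirected, weighted (default weight 1.0), simple (no self-loops, no
parallel edges), and symmetric by construction.  All downstream matrices
and embeddings are aligned to this node order.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["Graph", "AliasTable", "load_edge_list", "load_gene_list", "write_edge_list"]


class Graph:
    """Undirected weighted network over gene identifiers.

    Parameters
    ----------
    nodes
        Gene identifiers in index order.
    adjacency
        Per-node list of ``(neighbor_index, weight)`` pairs; must be
        symmetric, simple, with strictly positive weights.
    """

    def __init__(self, nodes: Sequence[str], adjacency: Sequence[Sequence[tuple[int, float]]]):
        if len(nodes) != len(adjacency):
            raise ValueError("nodes and adjacency must have the same length")
        self.nodes: list[str] = list(nodes)
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        self._adj: list[list[tuple[int, float]]] = [list(a) for a in adjacency]
        self._neighbor_sets: list[set[int]] | None = None
        n_entries = sum(len(a) for a in self._adj)
        if n_entries % 2 != 0:
            raise ValueError("adjacency is not symmetric (odd entry count)")
        self.n_edges: int = n_entries // 2

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Sequence[str] | None = None,
    ) -> "Graph":
        """Build a Graph from ``(u, v, weight)`` triples.

        Self-loops are dropped; for duplicate edges the first weight is
        kept.  Node order is first appearance (edge order), or the
        explicit ``nodes`` sequence, which may include isolated nodes.
        """
        order: list[str] = []
        index: dict[str, int] = {}
        if nodes is not None:
            order = list(nodes)
            index = {g: i for i, g in enumerate(order)}

        def idx(g: str) -> int:
            if g not in index:
                index[g] = len(order)
                order.append(g)
            return index[g]

        seen: set[tuple[int, int]] = set()
        pairs: list[tuple[int, int, float]] = []
        n_self, n_dup = 0, 0
        for u, v, w in edges:
            if u == v:
                n_self += 1
                continue
            i, j = idx(u), idx(v)
            key = (i, j) if i < j else (j, i)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            if w <= 0 or not np.isfinite(w):
                raise ValueError(f"non-positive or non-finite edge weight {w} on ({u}, {v})")
            pairs.append((key[0], key[1], float(w)))
        if n_self or n_dup:
            logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
        adj: list[list[tuple[int, float]]] = [[] for _ in order]
        for i, j, w in pairs:
            adj[i].append((j, w))
            adj[j].append((i, w))
        return cls(order, adj)

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def neighbors(self, node: int) -> list[tuple[int, float]]:
        """Stable-ordered ``(neighbor, weight)`` list; empty for isolated nodes."""
        if not 0 <= node < self.n_nodes:
            raise IndexError(f"node index {node} out of range [0, {self.n_nodes})")
        return self._adj[node]

    def neighbor_set(self, node: int) -> set[int]:
        if self._neighbor_sets is None:
            self._neighbor_sets = [{j for j, _ in a} for a in self._adj]
        return self._neighbor_sets[node]

    def degree(self, node: int) -> int:
        return len(self.neighbors(node))

    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self._adj], dtype=np.int64)

    def has_edge(self, u: int, v: int) -> bool:
        return v in self.neighbor_set(u)

    def isolated_nodes(self) -> np.ndarray:
        """Indices of degree-0 nodes."""
        return np.nonzero(self.degrees() == 0)[0]

    def edges(self) -> Iterable[tuple[int, int, float]]:
        """Each undirected edge once, with i < j."""
        for i, a in enumerate(self._adj):
            for j, w in a:
                if i < j:
                    yield i, j, w

    def to_scipy_sparse(self, weighted: bool = True) -> sp.csr_matrix:
        """Symmetric CSR adjacency matrix aligned to the node index."""
        rows, cols, vals = [], [], []
        for i, a in enumerate(self._adj):
            for j, w in a:
                rows.append(i)
                cols.append(j)
                vals.append(w if weighted else 1.0)
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_nodes, self.n_nodes), dtype=np.float64
        )

    def subgraph_lcc(self) -> "Graph":
        """Largest connected component, preserving relative node order."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from((i, j) for i, j, _ in self.edges())
        if self.n_nodes == 0:
            return Graph([], [])
        cc = max(nx.connected_components(g), key=len)
        keep = sorted(cc)
        names = [self.nodes[i] for i in keep]
        return Graph.from_edges(
            ((self.nodes[i], self.nodes[j], w) for i, j, w in self.edges() if i in cc and j in cc),
            nodes=names,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.nodes == other.nodes and {
            (i, j, w) for i, j, w in self.edges()
        } == {(i, j, w) for i, j, w in other.edges()}


class AliasTable:
    """Walker alias method for O(1) sampling from a discrete distribution.

    Construction is O(size); each draw uses two uniforms.  The draw
    distribution equals ``weights / weights.sum()`` exactly up to float
    rounding.
    """

    def __init__(self, weights: Sequence[float] | np.ndarray):
        w = np.asarray(weights, dtype=np.float64)
        if w.size == 0:
            raise ValueError("weights must be non-empty")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be positive and finite")
        self.size = w.size
        p = w * (self.size / w.sum())
        prob = np.zeros(self.size)
        alias = np.zeros(self.size, dtype=np.int64)
        small = [i for i in range(self.size) if p[i] < 1.0]
        large = [i for i in range(self.size) if p[i] >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            prob[s] = p[s]
            alias[s] = l
            p[l] = p[l] - (1.0 - p[s])
            (small if p[l] < 1.0 else large).append(l)
        for i in large + small:  # numerical leftovers
            prob[i] = 1.0
        self.prob = prob
        self.alias = alias

    def draw(self, rng: np.random.Generator) -> int:
        """One index from the table's distribution."""
        i = int(rng.integers(self.size))
        return i if rng.random() < self.prob[i] else int(self.alias[i])

    def draw_many(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Vectorized draws (same distribution, different stream use than draw)."""
        i = rng.integers(self.size, size=size)
        u = rng.random(size)
        return np.where(u < self.prob[i], i, self.alias[i])


def alias_draw(table: AliasTable, rng: np.random.Generator) -> int:
    """Functional form of :meth:`AliasTable.draw`."""
    return table.draw(rng)


def load_edge_list(path: str | Path, weighted: bool = False) -> Graph:
    """Load an undirected edge list: ``geneA geneB [weight]`` per line.

    Any whitespace run delimits tokens; lines starting with ``#`` are
    comments.  Duplicate edges keep their first weight; self-loops are
    dropped (both logged).  Node order is first appearance.  An empty
    file yields a valid empty Graph.
    """
    path = Path(path)

    def _parse():
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                toks = line.split()
                if len(toks) < 2:
                    raise ValueError(f"{path}:{lineno}: expected at least 2 tokens, got {len(toks)}")
                w = 1.0
                if weighted and len(toks) >= 3:
                    try:
                        w = float(toks[2])
                    except ValueError as e:
                        raise ValueError(f"{path}:{lineno}: bad weight {toks[2]!r}") from e
                    if w <= 0 or not np.isfinite(w):
                        raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
                yield toks[0], toks[1], w

    return Graph.from_edges(_parse())


def write_edge_list(graph: Graph, path: str | Path, weighted: bool = False) -> None:
    """Write each undirected edge once; isolated nodes are not representable."""
    with open(path, "w") as fh:
        for i, j, w in graph.edges():
            if weighted:
                fh.write(f"{graph.nodes[i]}\t{graph.nodes[j]}\t{w!r}\n")
            else:
                fh.write(f"{graph.nodes[i]}\t{graph.nodes[j]}\n")


def load_gene_list(path: str | Path) -> set[str]:
    """Load a gene list, one identifier per line; ``#`` comments allowed.

    Returns the de-duplicated set.  An empty result is an error: a
    disease gene set must be non-empty.
    """
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split()[0])
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes
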