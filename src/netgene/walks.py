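"""Random-walk corpus generation: uniform (DeepWalk) and (p,q)-biased
second-order (node2vec) walks.

The node2vec bias on a step from ``cur`` given the previous node
``prev`` multiplies each edge weight by alpha = 1/p if the candidate is
``prev`` itself, 1 if the candidate is adjacent to ``prev``, and 1/q
otherwise.  With p = q = 1 every step reduces to the first-order
weight-proportional step, i.e. DeepWalk on an unweighted graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import AliasTable, Graph

__all__ = ["WalkConfig", "WalkCorpus", "node2vec_step_distribution", "generate_walks", "context_pairs"]

# Precompute one alias table per directed edge only below this size.
_MAX_PRECOMPUTED_DIRECTED_EDGES = 1_000_000


@dataclass
class WalkConfig:
    """Walk-generation hyperparameters.

    ``strategy="deepwalk"`` is exactly ``node2vec`` with p = q = 1.
    Defaults (10 walks per node, length 80) are the settings standard in
    the network-embedding literature.
    """

    walks_per_node: int = 10
    walk_length: int = 80
    strategy: str = "node2vec"  # {"deepwalk", "node2vec"}
    p: float = 1.0
    q: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_node < 1 or self.walk_length < 2:
            raise ValueError("need walks_per_node >= 1 and walk_length >= 2")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.strategy not in ("deepwalk", "node2vec"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @property
    def effective_pq(self) -> tuple[float, float]:
        return (1.0, 1.0) if self.strategy == "deepwalk" else (self.p, self.q)


@dataclass
class WalkCorpus:
    """List of node-index sequences; the skip-gram training corpus."""

    walks: list[list[int]]
    n_nodes: int

    def __len__(self) -> int:
        return len(self.walks)

    def token_count(self) -> int:
        return sum(len(w) for w in self.walks)

    def node_frequencies(self) -> np.ndarray:
        freq = np.zeros(self.n_nodes, dtype=np.int64)
        for w in self.walks:
            np.add.at(freq, w, 1)
        return freq


def node2vec_step_distribution(
    graph: Graph, prev: int, cur: int, p: float, q: float
) -> np.ndarray:
    """Transition probabilities over ``graph.neighbors(cur)`` given ``prev``.

    Returns a vector aligned to the neighbor list order, summing to 1.
    """
    nbrs = graph.neighbors(cur)
    if not nbrs:
        raise ValueError(f"node {cur} is isolated; no step distribution")
    prev_nbrs = graph.neighbor_set(prev)
    biased = np.empty(len(nbrs))
    for k, (j, w) in enumerate(nbrs):
        if j == prev:
            alpha = 1.0 / p
        elif j in prev_nbrs:
            alpha = 1.0
        else:
            alpha = 1.0 / q
        biased[k] = w * alpha
    return biased / biased.sum()


def _first_order_tables(graph: Graph) -> list[AliasTable | None]:
    tables: list[AliasTable | None] = []
    for i in range(graph.n_nodes):
        nbrs = graph.neighbors(i)
        tables.append(AliasTable([w for _, w in nbrs]) if nbrs else None)
    return tables


def generate_walks(graph: Graph, config: WalkConfig) -> WalkCorpus:
    """Generate ``walks_per_node`` truncated random walks from every
    non-isolated node.

    Walks are grouped in passes: each pass visits all eligible start
    nodes in a seeded shuffled order.  A walk ends early only if the
    current node has no onward neighbor (impossible on an undirected
    graph once entered via an edge, but guarded).  Deterministic under
    a fixed seed.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(config.seed)
    p, q = config.effective_pq
    first_order = p == 1.0 and q == 1.0
    node_tables = _first_order_tables(graph)

    edge_tables: dict[tuple[int, int], AliasTable] | None = None
    if not first_order and 2 * graph.n_edges <= _MAX_PRECOMPUTED_DIRECTED_EDGES:
        edge_tables = {}
        for u in range(graph.n_nodes):
            for v, _ in graph.neighbors(u):
                edge_tables[(u, v)] = AliasTable(
                    node2vec_step_distribution(graph, u, v, p, q)
                )

    starts = np.nonzero(graph.degrees() > 0)[0]
    walks: list[list[int]] = []
    for _ in range(config.walks_per_node):
        order = starts[rng.permutation(starts.size)]
        for s in order:
            walk = [int(s)]
            while len(walk) < config.walk_length:
                cur = walk[-1]
                nbrs = graph.neighbors(cur)
                if not nbrs:
                    break
                if len(walk) == 1 or first_order:
                    k = node_tables[cur].draw(rng)
                else:
                    prev = walk[-2]
                    if edge_tables is not None:
                        k = edge_tables[(prev, cur)].draw(rng)
                    else:
                        dist = node2vec_step_distribution(graph, prev, cur, p, q)
                        k = int(rng.choice(len(nbrs), p=dist))
                walk.append(nbrs[k][0])
            walks.append(walk)
    return WalkCorpus(walks=walks, n_nodes=graph.n_nodes)


def context_pairs(walk: list[int], window: int) -> list[tuple[int, int]]:
    """All (center, context) pairs with positional distance <= window,
    truncated at walk boundaries."""
    if window < 1:
        raise ValueError("window must be >= 1")
    pairs: list[tuple[int, int]] = []
    n = len(walk)
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        for j in range(lo, hi):
            if j != i:
                pairs.append((walk[i], walk[j]))
    return pairs


def corpus_pair_arrays(corpus: WalkCorpus, window: int, order: np.ndarray | None = None):
    """Vectorized (centers, contexts) index arrays for a whole corpus.

    ``order`` optionally permutes the walks (per-epoch shuffling);
    pairs within a walk stay in walk order.
    """
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    walk_ids = order if order is not None else range(len(corpus.walks))
    for wi in walk_ids:
        walk = np.asarray(corpus.walks[wi], dtype=np.int64)
        n = walk.size
        if n < 2:
            continue
        for off in range(1, min(window, n - 1) + 1):
            # symmetric offsets handled as two directed streams
            centers.append(walk[:-off])
            contexts.append(walk[off:])
            centers.append(walk[off:])
            contexts.append(walk[:-off])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)
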