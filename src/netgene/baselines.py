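"""Classical guilt-by-association scorers used as comparison baselines:
random walk with restart (RWR), shortest path length (SPL), and
Euclidean distance between adjacency profiles (ED).

Each maps (graph, seed gene set) to one score per node, oriented so
that higher means more disease-like.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import Graph

__all__ = ["ScoreVector", "rwr_scores", "spl_scores", "ed_scores", "write_scores"]


@dataclass
class ScoreVector:
    """Per-node scores aligned to the Graph index."""

    scores: np.ndarray
    higher_is_better: bool
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")


def _seed_indices(graph: Graph, seeds) -> np.ndarray:
    idx = sorted(graph.index[g] for g in seeds if g in graph.index)
    if not idx:
        raise ValueError("no seed gene is present in the graph")
    return np.asarray(idx, dtype=np.int64)


def rwr_scores(
    graph: Graph,
    seeds,
    restart_prob: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> ScoreVector:
    """Random walk with restart from a uniform seed vector.

    Iterates ``s <- (1 - r) * M s + r * e`` with M the column-stochastic
    adjacency and e uniform over the seeds, until the L1 change drops
    below ``tol``.  Mass on dangling (degree-0) columns is redistributed
    to the seed vector, so the stationary vector sums to 1.  The default
    restart probability 0.7 is the value standard in disease-gene RWR.
    """
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError("restart_prob must be in (0, 1]")
    seed_idx = _seed_indices(graph, seeds)
    n = graph.n_nodes
    e = np.zeros(n)
    e[seed_idx] = 1.0 / seed_idx.size
    if restart_prob == 1.0:
        return ScoreVector(e, higher_is_better=True, method="rwr")

    A = graph.to_scipy_sparse()
    colsum = np.asarray(A.sum(axis=0)).ravel()
    dangling = colsum == 0
    inv = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, colsum))
    M = A @ sp.diags(inv)  # column-stochastic on non-dangling columns

    s = e.copy()
    r = restart_prob
    for _ in range(max_iter):
        s_new = (1 - r) * (M @ s + s[dangling].sum() * e) + r * e
        if np.abs(s_new - s).sum() < tol:
            s = s_new
            break
        s = s_new
    return ScoreVector(s, higher_is_better=True, method="rwr")


def spl_scores(graph: Graph, seeds, aggregation: str = "min") -> ScoreVector:
    """Shortest-path-length proximity to the seed set.

    Unweighted BFS hop distance to the nearest seed (``min``, default)
    or the mean distance over seeds, converted to the higher-is-better
    score ``1 / (1 + distance)``; nodes unreachable from every seed get
    score 0.
    """
    seed_idx = _seed_indices(graph, seeds)
    n = graph.n_nodes
    if aggregation == "min":
        dist = np.full(n, np.inf)
        dq: deque[int] = deque()
        for s in seed_idx:
            dist[s] = 0.0
            dq.append(int(s))
        while dq:
            u = dq.popleft()
            for v, _ in graph.neighbors(u):
                if dist[v] == np.inf:
                    dist[v] = dist[u] + 1
                    dq.append(v)
    elif aggregation == "mean":
        total = np.zeros(n)
        reached = np.zeros(n, dtype=np.int64)
        for s in seed_idx:
            d = np.full(n, np.inf)
            d[s] = 0.0
            dq = deque([int(s)])
            while dq:
                u = dq.popleft()
                for v, _ in graph.neighbors(u):
                    if d[v] == np.inf:
                        d[v] = d[u] + 1
                        dq.append(v)
            ok = np.isfinite(d)
            total[ok] += d[ok]
            reached[ok] += 1
        dist = np.where(reached == seed_idx.size, total / np.maximum(reached, 1), np.inf)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    scores = np.where(np.isfinite(dist), 1.0 / (1.0 + dist), 0.0)
    return ScoreVector(scores, higher_is_better=True, method="spl")


def ed_scores(graph: Graph, seeds) -> ScoreVector:
    """Euclidean distance between binary adjacency profiles.

    score(v) = -mean over seeds s of ||A_v - A_s||_2, where A_x is node
    x's 0/1 adjacency row; negation makes higher mean more similar.
    """
    seed_idx = _seed_indices(graph, seeds)
    A = graph.to_scipy_sparse(weighted=False)
    deg = np.asarray(A.sum(axis=1)).ravel()
    # ||a - b||^2 = deg(a) + deg(b) - 2 a.b  for binary rows
    cross = np.asarray((A @ A[seed_idx].T).todense())  # (n, n_seeds)
    d2 = deg[:, None] + deg[seed_idx][None, :] - 2.0 * cross
    d2 = np.maximum(d2, 0.0)
    scores = -np.sqrt(d2).mean(axis=1)
    return ScoreVector(scores, higher_is_better=True, method="ed")


def write_scores(sv: ScoreVector, graph: Graph, path) -> None:
    """Two-column TSV: gene identifier, score."""
    with open(path, "w") as fh:
        for name, s in zip(graph.nodes, sv.scores):
            fh.write(f"{name}\t{s:.10g}\n")
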