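"""Brute-force reference implementations used as independent oracles.

Deliberately naive (loops, direct solves, exhaustive sweeps) and kept
independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np

from netgene.graph import Graph


def rwr_solve(graph: Graph, seed_idx: np.ndarray, r: float) -> np.ndarray:
    """Direct linear-system solution of the restart stationary equation:
    (I - (1 - r) M) s = r e, with M the column-stochastic adjacency and
    dangling columns redistributing to e."""
    n = graph.n_nodes
    e = np.zeros(n)
    e[seed_idx] = 1.0 / len(seed_idx)
    M = np.zeros((n, n))
    for j in range(n):
        nbrs = graph.neighbors(j)
        total = sum(w for _, w in nbrs)
        if total == 0:
            M[:, j] = e  # dangling mass goes back to the seeds
        else:
            for i, w in nbrs:
                M[i, j] = w / total
    return np.linalg.solve(np.eye(n) - (1.0 - r) * M, r * e)


def auroc_pairs(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordant-pair counting with ties worth 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def auprc_sweep(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise precision-recall summation over descending unique
    score thresholds: sum (R_i - R_{i-1}) * P_i."""
    n_pos = int((labels == 1).sum())
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores.tolist()), reverse=True):
        kept = scores >= t
        tp = int(((labels == 1) & kept).sum())
        precision = tp / int(kept.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def bfs_distances(graph: Graph, sources: list[int]) -> np.ndarray:
    """Naive repeated single-source BFS, min over sources."""
    n = graph.n_nodes
    best = np.full(n, np.inf)
    for s in sources:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v, _ in graph.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            best[v] = min(best[v], d)
    return best


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function, element by element."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        f_hi = f()
        x[idx] = orig - eps
        f_lo = f()
        x[idx] = orig
        g[idx] = (f_hi - f_lo) / (2.0 * eps)
        it.iternext()
    return g


def relative_error(a: np.ndarray, b: np.ndarray) -> float:
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-12)
    return float(np.abs(a - b).max() / denom)
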