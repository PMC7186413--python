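"""LINE embedding: first- and second-order proximity via edge sampling.

First-order proximity models the probability of a direct edge as
``P1(i, j) = sigma(u_i . u_j)``; second-order proximity models a node's
context distribution as a softmax over context vectors,
``P2(j | i) = exp(ub_j . u_i) / sum_k exp(ub_k . u_i)``.  Minimizing the
KL divergence between these model distributions and the empirical
(edge-weight) distributions is done by sampling edges proportionally to
their weight and applying negative sampling (noise distribution
proportional to degree^(3/4)); the full softmax is kept only as an
exact evaluation path for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .embedding import Embedding
from .graph import AliasTable, Graph
from .skipgram import sgns_pair_grads, sgns_pair_loss

__all__ = [
    "LineConfig",
    "first_order_prob",
    "second_order_prob",
    "train_line",
    "line1_pair_loss",
    "line1_pair_grads",
]


@dataclass
class LineConfig:
    """LINE hyperparameters.

    ``order="concat-both"`` trains the two objectives independently at
    dim/2 each, L2-normalizes the halves row-wise, and concatenates.
    ``total_samples`` defaults to 100 x n_edges when left as None.
    """

    dim: int = 128
    order: str = "concat-both"  # {"first", "second", "concat-both"}
    total_samples: int | None = None
    negatives: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.negatives < 1 or self.learning_rate <= 0:
            raise ValueError("invalid LINE hyperparameters")
        if self.order not in ("first", "second", "concat-both"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.order == "concat-both" and self.dim % 2 != 0:
            raise ValueError("concat-both requires an even dim")


def first_order_prob(u_i: np.ndarray, u_j: np.ndarray) -> float:
    """sigmoid(u_i . u_j); symmetric in its arguments."""
    return float(expit(np.dot(u_i, u_j)))


def second_order_prob(center: int, context: int, embedding: Embedding) -> float:
    """Exact softmax P2(context | center) over all context vectors.

    Intended for small graphs and testing; training never materializes
    this normalization.
    """
    if embedding.context_vectors is None:
        raise ValueError("embedding has no context vectors")
    scores = embedding.context_vectors @ embedding.vectors[center]
    scores -= scores.max()  # overflow guard
    e = np.exp(scores)
    return float(e[context] / e.sum())


# First-order loss/grads: same negative-sampling form as skip-gram but the
# "context" vectors are the node vectors themselves (one shared matrix).
line1_pair_loss = sgns_pair_loss
line1_pair_grads = sgns_pair_grads


def _edge_arrays(graph: Graph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    src, dst, w = [], [], []
    for i, j, wt in graph.edges():
        src.append(i)
        dst.append(j)
        w.append(wt)
    return (
        np.asarray(src, dtype=np.int64),
        np.asarray(dst, dtype=np.int64),
        np.asarray(w, dtype=np.float64),
    )


_N_LOSS_CHUNKS = 20  # loss-trace resolution for the edge-sampling SGD


def _train_order(
    graph: Graph,
    dim: int,
    order: str,
    total_samples: int,
    k: int,
    lr0: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None, list[float]]:
    from ._kernels import sgns_epoch_kernel

    n = graph.n_nodes
    src, dst, w = _edge_arrays(graph)
    edge_table = AliasTable(w)
    deg = graph.degrees().astype(np.float64)
    pos_deg = np.nonzero(deg > 0)[0]
    noise = AliasTable(deg[pos_deg] ** 0.75)

    W = ((rng.random((n, dim)) - 0.5) / dim).astype(np.float32)
    C = np.zeros((n, dim), dtype=np.float32) if order == "second" else None
    out = C if order == "second" else W
    loss_history: list[float] = []
    done = 0
    chunk = max(1, total_samples // _N_LOSS_CHUNKS)
    while done < total_samples:
        b = min(chunk, total_samples - done)
        e = edge_table.draw_many(rng, b)
        flip = rng.random(b) < 0.5  # undirected edge -> random direction
        ci = np.where(flip, dst[e], src[e])
        cj = np.where(flip, src[e], dst[e])
        kernel_seed = int(rng.integers(2**31))
        loss = sgns_epoch_kernel(
            W, out, ci, cj, noise.prob, noise.alias, pos_deg,
            k, lr0, lr0 * 1e-4, total_samples, done, kernel_seed,
        )
        loss_history.append(loss / b)
        done += b
    return (
        W.astype(np.float64),
        C.astype(np.float64) if C is not None else None,
        loss_history,
    )


def train_line(graph: Graph, config: LineConfig) -> Embedding:
    """Train LINE on ``graph`` per ``config``.

    Isolated nodes are never sampled; they keep their initialization and
    are flagged unvisited.  Raises on an edgeless graph.
    """
    if graph.n_edges == 0:
        raise ValueError("LINE requires a graph with at least one edge")
    rng = np.random.default_rng(config.seed)
    total = config.total_samples if config.total_samples is not None else 100 * graph.n_edges
    visited = graph.degrees() > 0

    if config.order in ("first", "second"):
        W, C, hist = _train_order(
            graph, config.dim, config.order, total, config.negatives,
            config.learning_rate, rng,
        )
        return Embedding(
            nodes=list(graph.nodes), vectors=W, context_vectors=C,
            visited=visited, loss_history=hist,
        )

    half = config.dim // 2
    W1, _, h1 = _train_order(
        graph, half, "first", total, config.negatives,
        config.learning_rate, rng,
    )
    W2, C2, h2 = _train_order(
        graph, half, "second", total, config.negatives,
        config.learning_rate, rng,
    )

    def _l2norm(m: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(m, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return m / nrm

    return Embedding(
        nodes=list(graph.nodes),
        vectors=np.hstack([_l2norm(W1), _l2norm(W2)]),
        context_vectors=None,
        visited=visited,
        loss_history=h1 + h2,
    )
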