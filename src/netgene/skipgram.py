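"""Skip-gram embedding training over a walk corpus.

The window objective — maximize the probability of a node's walk
context given its vector — is optimized with negative sampling: for
each observed (center, context) pair, the loss is

    L = -log sigma(u_o . v_c) - sum_k log sigma(-u_nk . v_c)

with v the input (center) vectors, u the context vectors, and k noise
nodes drawn from the corpus unigram distribution raised to the 3/4
power.  Training is single-threaded per-pair SGD with a linearly
decaying learning rate (the word2vec schedule), deterministic under a
fixed seed; the hot loop is JIT-compiled in :mod:`netgene._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .embedding import Embedding
from .graph import AliasTable, Graph
from .walks import WalkCorpus, corpus_pair_arrays

__all__ = ["SkipGramConfig", "train_skipgram", "sgns_pair_loss", "sgns_pair_grads"]


@dataclass
class SkipGramConfig:
    """Skip-gram hyperparameters (literature-standard defaults)."""

    dim: int = 128
    window: int = 10
    epochs: int = 5
    negatives: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.negatives < 1:
            raise ValueError("dim, window and negatives must be >= 1")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1 and learning_rate > 0 required")


def sgns_pair_loss(v_c: np.ndarray, u_o: np.ndarray, u_negs: np.ndarray) -> float:
    """Negative-sampling loss for one (center, context) pair.

    ``u_negs`` is a (k, d) matrix of noise context vectors.
    """
    pos = float(np.dot(v_c, u_o))
    negs = u_negs @ v_c
    # -log sigma(x) written via logaddexp for stability
    return float(np.logaddexp(0.0, -pos) + np.logaddexp(0.0, negs).sum())


def sgns_pair_grads(
    v_c: np.ndarray, u_o: np.ndarray, u_negs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`sgns_pair_loss` w.r.t. (v_c, u_o, u_negs)."""
    s_pos = expit(np.dot(v_c, u_o))
    s_negs = expit(u_negs @ v_c)
    g_vc = (s_pos - 1.0) * u_o + s_negs @ u_negs
    g_uo = (s_pos - 1.0) * v_c
    g_unegs = s_negs[:, None] * v_c[None, :]
    return g_vc, g_uo, g_unegs


def _noise_table(corpus: WalkCorpus) -> tuple[AliasTable, np.ndarray]:
    freq = corpus.node_frequencies().astype(np.float64)
    visited = freq > 0
    w = freq[visited] ** 0.75
    return AliasTable(w), np.nonzero(visited)[0]


def train_skipgram(
    corpus: WalkCorpus, graph: Graph, config: SkipGramConfig
) -> Embedding:
    """Train skip-gram with negative sampling over ``corpus``.

    Nodes never appearing in the corpus (isolated nodes) keep their
    uniform(-0.5/d, 0.5/d) initialization and are flagged unvisited in
    the returned Embedding's coverage report.  The per-epoch mean pair
    loss is exposed as ``loss_history``.
    """
    if not corpus.walks or corpus.token_count() == 0:
        raise ValueError("empty corpus")
    from ._kernels import sgns_epoch_kernel

    n, d = graph.n_nodes, config.dim
    rng = np.random.default_rng(config.seed)

    W_in = ((rng.random((n, d)) - 0.5) / d).astype(np.float32)
    W_out = np.zeros((n, d), dtype=np.float32)

    noise, visited_idx = _noise_table(corpus)
    visited = np.zeros(n, dtype=bool)
    visited[visited_idx] = True

    # total pair count drives the linear learning-rate decay
    pairs_per_epoch = sum(
        2 * sum(len(w) - off for off in range(1, min(config.window, len(w) - 1) + 1))
        for w in corpus.walks
        if len(w) >= 2
    )
    total_pairs = max(1, pairs_per_epoch * config.epochs)
    processed = 0
    loss_history: list[float] = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(corpus.walks))
        centers, contexts = corpus_pair_arrays(corpus, config.window, order)
        kernel_seed = int(rng.integers(2**31))
        loss = sgns_epoch_kernel(
            W_in, W_out, centers, contexts,
            noise.prob, noise.alias, visited_idx,
            config.negatives, config.learning_rate, config.learning_rate * 1e-4,
            total_pairs, processed, kernel_seed,
        )
        processed += centers.size
        loss_history.append(loss / max(1, centers.size))

    return Embedding(
        nodes=list(graph.nodes),
        vectors=W_in.astype(np.float64),
        context_vectors=W_out.astype(np.float64),
        visited=visited,
        loss_history=loss_history,
    )
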