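"""Per-node embedding container and word2vec-style text I/O.

The on-disk format is the plain-text word2vec convention: a header line
``n_nodes dim`` followed by one ``identifier v1 ... vd`` line per node.
Only the input vectors are serialized; context vectors are a training
artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Embedding", "read_word2vec", "write_word2vec"]


@dataclass
class Embedding:
    """Node embedding matrix aligned to a Graph's node order.

    Attributes
    ----------
    nodes
        Gene identifiers, row order of the matrices.
    vectors
        ``(n, d)`` input vectors (the representation used downstream).
    context_vectors
        ``(n, d)`` context ("output") vectors from skip-gram / LINE
        second-order training, or ``None`` where not applicable.
    visited
        Boolean mask: False rows never received a gradient update and
        still hold their initialization (e.g. isolated nodes).
    """

    nodes: list[str]
    vectors: np.ndarray
    context_vectors: np.ndarray | None = None
    visited: np.ndarray | None = None
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.nodes):
            raise ValueError("vectors must be (n_nodes, dim)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")
        if self.visited is None:
            self.visited = np.ones(len(self.nodes), dtype=bool)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]

    def coverage_report(self) -> dict:
        """How many rows were actually trained vs. left at initialization."""
        n_unvisited = int((~self.visited).sum())
        return {
            "n_nodes": self.n_nodes,
            "n_trained": self.n_nodes - n_unvisited,
            "n_untrained": n_unvisited,
            "untrained_nodes": [self.nodes[i] for i in np.nonzero(~self.visited)[0][:50]],
        }

    def rows(self, indices: np.ndarray) -> np.ndarray:
        return self.vectors[np.asarray(indices, dtype=np.int64)]


def write_word2vec(emb: Embedding, path: str | Path) -> None:
    """Write ``n dim`` header then one ``identifier v1 ... vd`` line per node."""
    with open(path, "w") as fh:
        fh.write(f"{emb.n_nodes} {emb.dim}\n")
        for name, row in zip(emb.nodes, emb.vectors):
            fh.write(name + " " + " ".join(f"{x:.8g}" for x in row) + "\n")


def read_word2vec(path: str | Path) -> Embedding:
    """Inverse of :func:`write_word2vec`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, d = int(header[0]), int(header[1])
        names: list[str] = []
        mat = np.empty((n, d), dtype=np.float64)
        for i in range(n):
            toks = fh.readline().split()
            if len(toks) != d + 1:
                raise ValueError(f"{path}: row {i} has {len(toks) - 1} values, expected {d}")
            names.append(toks[0])
            mat[i] = [float(t) for t in toks[1:]]
    return Embedding(nodes=names, vectors=mat)
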