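"""Numba JIT kernels for the negative-sampling SGD inner loops.

The skip-gram and LINE objectives update two embedding matrices once
per observed (center, context) pair; that per-pair loop is the hot path
and is compiled here.  Kernels are single-threaded and sequential, so
results are bit-reproducible for a fixed seed.  Embedding matrices are
float32 (the convention for these trainers); losses accumulate in
float64.

Negative samples are drawn inside the kernel from an alias table
(``prob``/``alias`` arrays) over the noise distribution, remapped to
node ids through ``node_map``.  The learning rate decays linearly from
``lr0`` to ``lr0 * 1e-4`` over the scheduled total number of pairs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sgns_epoch_kernel"]


@njit(cache=True, fastmath=True)
def _log1pexp(z: float) -> float:
    # log(1 + exp(z)), overflow-safe
    if z > 30.0:
        return z
    if z < -30.0:
        return 0.0
    return np.log(1.0 + np.exp(z))


@njit(cache=True, fastmath=True)
def _alias_draw(prob, alias, u1: float, u2: float) -> int:
    i = int(u1 * prob.shape[0])
    if i >= prob.shape[0]:  # guard u1 == 1.0
        i = prob.shape[0] - 1
    if u2 < prob[i]:
        return i
    return alias[i]


@njit(cache=True, fastmath=True)
def sgns_epoch_kernel(
    W_in,        # (n, d) float32, updated in place
    W_out,       # (n, d) float32, updated in place (may alias W_in for LINE-1)
    centers,     # (m,) int64
    contexts,    # (m,) int64
    prob,        # alias-table probabilities over noise distribution
    alias,       # alias-table aliases
    node_map,    # noise index -> node id
    k: int,      # negatives per pair
    lr0: float,
    lr_min: float,
    total_pairs: int,   # schedule length for the linear decay
    processed0: int,    # pairs already processed before this call
    seed: int,
) -> float:
    """One pass of pairwise SGD; returns the summed pre-update loss."""
    np.random.seed(seed)
    d = W_in.shape[1]
    g_v = np.empty(d, dtype=np.float32)
    v = np.empty(d, dtype=np.float32)
    loss = 0.0
    for idx in range(centers.shape[0]):
        frac = (processed0 + idx) / total_pairs
        lr = lr0 * (1.0 - frac)
        if lr < lr_min:
            lr = lr_min
        c = centers[idx]
        o = contexts[idx]
        for t in range(d):
            v[t] = W_in[c, t]
            g_v[t] = 0.0
        # positive pair
        dot = 0.0
        for t in range(d):
            dot += v[t] * W_out[o, t]
        loss += _log1pexp(-dot)
        g = 1.0 / (1.0 + np.exp(-dot)) - 1.0  # sigma(dot) - 1
        for t in range(d):
            g_v[t] += g * W_out[o, t]
            W_out[o, t] -= lr * g * v[t]
        # negative samples
        for s in range(k):
            ni = node_map[_alias_draw(prob, alias, np.random.random(), np.random.random())]
            dot = 0.0
            for t in range(d):
                dot += v[t] * W_out[ni, t]
            loss += _log1pexp(dot)
            g = 1.0 / (1.0 + np.exp(-dot))  # sigma(dot)
            for t in range(d):
                g_v[t] += g * W_out[ni, t]
                W_out[ni, t] -= lr * g * v[t]
        for t in range(d):
            W_in[c, t] -= lr * g_v[t]
    return loss
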