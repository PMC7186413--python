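"""Deterministic seed fan-out.

Every stochastic stage receives a child seed derived from the master
seed by hashing ``master:stage:index``, giving independent but fully
reproducible streams regardless of stage execution order.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(master: int, stage: str, index: int = 0) -> int:
    """A 31-bit seed for one named stage under a master seed."""
    digest = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
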