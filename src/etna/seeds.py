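"""Deterministic named seed streams.

All randomness in the package flows from one master seed. Stage seeds are
derived by hashing the master seed together with a stream name, so adding a
new consumer never perturbs existing streams, and streams can be keyed by
content hashes (used by the alignment module to make results independent of
argument order).
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "stream"]


def derive_seed(master: int, *names: str) -> int:
    """Derive a child seed (< 2**31) from a master seed and stream names."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for name in names:
        h.update(b"\x00")
        h.update(str(name).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def stream(master: int, *names: str) -> np.random.Generator:
    """A fresh PCG64 generator for the named stream."""
    return np.random.default_rng(derive_seed(master, *names))
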