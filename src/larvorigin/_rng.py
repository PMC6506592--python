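"""Deterministic per-component random streams.

One root seed drives a whole run; each component derives its own child seed
by hashing a fixed text label, so any stage can be re-run in isolation and
still see the same stream it saw inside the full pipeline.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(root_seed: int, label: str) -> int:
    """Derive a stable 31-bit child seed from ``root_seed`` and a label."""
    digest = hashlib.sha256(f"{int(root_seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def child_rng(root_seed: int, label: str) -> np.random.Generator:
    """A numpy Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(root_seed, label))
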