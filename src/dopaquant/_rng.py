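"""Named, reproducible random substreams.

All stochastic stages derive their generator from a single master seed plus a
stage name, so any stage can be rerun independently and bit-identically.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    # stable 64-bit key from the stage name; not security-sensitive
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator deterministically keyed by (master_seed, name)."""
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(_name_key(name),))
    return np.random.default_rng(ss)
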