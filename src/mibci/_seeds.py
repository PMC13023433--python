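"""Deterministic seed fan-out.

A master seed is combined with a path of names (stage, subject, trial ...)
via SHA-256 so that every stage draws from an independent stream and adding
a new stage never shifts the randomness of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master_seed: int, *names) -> int:
    """A 31-bit seed derived from ``master_seed`` and a name path."""
    key = ":".join([str(int(master_seed))] + [str(n) for n in names])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(master_seed: int, *names) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *names))
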