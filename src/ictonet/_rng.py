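"""Deterministic seed derivation.

Every stochastic stage receives a seed derived from a single master seed, so
whole-pipeline runs are reproducible and individual stages can be re-run in
isolation with the same randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]

_MAX_SEED = 2**31 - 1


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & _MAX_SEED
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seed(master: int, *keys: int | str) -> int:
    """Derive a child seed (< 2**31) from ``master`` and a key path.

    Distinct key paths give statistically independent child seeds; the same
    path always gives the same child.
    """
    seq = np.random.SeedSequence([int(master)] + [_key_to_int(k) for k in keys])
    return int(seq.generate_state(1, dtype=np.uint32)[0]) & _MAX_SEED
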