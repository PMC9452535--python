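"""Deterministic, order-independent random substreams.

Every stochastic step draws from a Generator keyed by the master seed plus
stable string tags (subject id, method name, stage). Adding a method or
reordering the loop therefore never perturbs any other cell's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def _tag(s: str) -> int:
    return zlib.crc32(s.encode("utf-8"))


def substream(master_seed: int, *keys: str | int) -> np.random.Generator:
    """Generator for the substream identified by (master_seed, *keys)."""
    entropy = [int(master_seed) & 0xFFFFFFFF]
    for k in keys:
        entropy.append(_tag(k) if isinstance(k, str) else int(k) & 0xFFFFFFFF)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))
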