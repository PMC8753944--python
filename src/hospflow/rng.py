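"""Named random-number substreams.

Every stochastic source in a replication (arrivals, type mix, each service
distribution) draws from its own stream, all derived from the replication
seed.  Keeping sources on separate streams supports common-random-numbers
comparisons between staffing candidates.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def substream(seed: int, name: str) -> np.random.Generator:
    """A reproducible generator for the named stochastic source."""
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, index: int) -> int:
    """Derive a per-replication integer seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))
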