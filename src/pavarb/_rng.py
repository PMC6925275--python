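"""Named RNG substreams derived from one global seed.

Every stochastic stage asks for its own substream by name, so adding a new
stage never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The entropy pool mixes the global seed with a CRC32 of each name, so
    ``substream(seed, "simulate", pid)`` is stable across runs and
    independent of call order.
    """
    entropy = [int(seed) & 0xFFFFFFFF] + [
        zlib.crc32(str(n).encode("utf-8")) for n in names
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))
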