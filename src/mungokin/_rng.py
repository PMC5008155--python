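"""Named random-number substreams.

All randomness in the package flows from a single integer seed; independent
stages draw from named substreams so results do not depend on the order in
which stages run (or on parallelisation).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator for stage ``name`` derived from the master ``seed``.

    The stream key is a CRC32 of the stage name, so the mapping is stable
    across processes and Python versions.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
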