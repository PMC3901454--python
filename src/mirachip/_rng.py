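"""Named, splittable random substreams.

One global seed drives the whole pipeline; each stage derives its own
independent generator from (seed, stage name) so that re-running a single
stage reproduces its output regardless of what ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name` derived from the global `seed`.

    The mapping is stable across sessions and platforms: the stage name is
    hashed with CRC-32 and used as a spawn key of a SeedSequence.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
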