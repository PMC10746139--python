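"""Named, reproducible random substreams.

All stochastic stages (receptor geometry, model perturbation, pose jitter,
correctness draws, bootstrap resampling) derive their generators from a single
root seed via named substreams, so any one stage can be re-run in isolation
and still reproduce exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The spawn key is derived from CRC32 hashes of the (stringified) names, so
    the mapping from ``(seed, names)`` to a bit stream is stable across runs,
    platforms and process boundaries.
    """
    key = tuple(zlib.crc32(str(n).encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))
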