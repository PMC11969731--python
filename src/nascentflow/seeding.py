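"""Seed-splitting rule shared by every stochastic component.

A single user-facing seed is expanded into independent per-component
substreams with :class:`numpy.random.SeedSequence` spawn keys.  Each
generator owns a fixed stream id, so adding a new generator never perturbs
the streams of existing ones.
"""

from __future__ import annotations

import numpy as np

# Fixed stream ids; append-only.
STREAM_TRANSCRIPTOME = 0
STREAM_SLAM = 1
STREAM_INTERACTOME = 2
STREAM_IPA = 3
STREAM_SAM = 4


def substream(seed: int, stream: int, *extra: int) -> np.random.Generator:
    """Return the RNG for component `stream` derived from the global `seed`.

    `extra` keys subdivide a component stream further (e.g. per sample).
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream), *map(int, extra)))
    return np.random.default_rng(ss)
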