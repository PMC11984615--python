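"""Seed handling.

Every stochastic entry point takes a ``seed`` that may be an int, a
``numpy.random.Generator``, or a ``SeedSequence``.  Experiment drivers expand a
single master seed into independent per-scenario / per-replicate substreams via
``SeedSequence.spawn``, so results are reproducible from (spec, seed) alone.
"""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Expand one master seed into ``n`` independent generators."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def spawn_seedseqs(seed, n: int) -> list[np.random.SeedSequence]:
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return ss.spawn(n)
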