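"""Deterministic seed derivation shared by all stochastic stages.

Every module that consumes randomness takes a single integer seed and, when
it needs several independent streams (replicate forests, CV folds, per-block
synthetic substreams), derives child seeds through ``spawn_seeds``. The
scheme is pure function of (base_seed, stream label), so results never
depend on execution order.
"""

from __future__ import annotations

import numpy as np

_MAX_SEED = 2**31 - 1


def spawn_seeds(base_seed: int, n: int, stream: int = 0) -> list[int]:
    """Derive ``n`` independent child seeds from ``base_seed``.

    ``stream`` separates families of children (e.g. replicate forests vs
    CV shuffles) drawn from the same base seed.
    """
    ss = np.random.SeedSequence([int(base_seed), int(stream)])
    return [int(s) % _MAX_SEED for s in ss.generate_state(n, dtype=np.uint64)]


def substream_rng(base_seed: int, *stream: int) -> np.random.Generator:
    """A Generator on the substream identified by the integer path ``stream``."""
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), *map(int, stream)]))
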