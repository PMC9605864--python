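"""Named random substreams derived from one master seed.

Every stochastic component draws from a generator obtained via
:func:`substream`, so adding Monte Carlo draws or reordering components
never perturbs the numbers of earlier draws.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = 0x7FFFFFFF  # keep all entropy below 2**31


def _key_to_int(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8")) & _MASK
    return int(key) & _MASK


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return an independent ``Generator`` for (master seed, named path).

    Keys may be strings (component names) or integers (draw indices); the
    same (seed, keys) pair always yields the same stream.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed) & _MASK,
        spawn_key=tuple(_key_to_int(k) for k in keys),
    )
    return np.random.default_rng(ss)
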