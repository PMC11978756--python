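"""Deterministic, named random substreams.

Every stochastic routine in the package draws from a :class:`numpy.random.Generator`
derived from one integer master seed plus a tuple of names (strings or ints).
Two substreams with different names are statistically independent, and adding a
new named stream never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _token(name) -> int:
    if isinstance(name, (int, np.integer)):
        return int(name) & 0xFFFFFFFF
    return zlib.crc32(str(name).encode("utf-8"))


def substream(seed: int, *names) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a sequence of stream names.

    Parameters
    ----------
    seed
        Master integer seed.
    names
        Any mix of strings and integers identifying the stream
        (e.g. ``substream(7, "coupling", origin_id, target_id)``).
    """
    entropy = [int(seed) & 0xFFFFFFFF] + [_token(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))
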