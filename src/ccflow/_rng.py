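"""Named random substreams.

Every stochastic operation in ccflow draws from a generator obtained via
:func:`substream`, so one top-level seed yields bit-reproducible output and
independent modules never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is derived from a CRC32 of ``name``, which is stable
    across platforms and Python versions.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
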