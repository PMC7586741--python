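"""Named, reproducible random streams.

All randomness in the package flows from a single integer seed.  Each
generated artifact draws from its own child stream, derived from the seed
plus a stable name, so that regenerating one file never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the stream identified by ``names``.

    The stream key is derived from CRC32 of the joined names, which is
    stable across processes and Python versions (unlike ``hash``).
    """
    key = zlib.crc32("/".join(names).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
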