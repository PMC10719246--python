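"""Named random-number streams.

Every stochastic component draws from a stream addressed by a path of names
(e.g. ``("jurisdiction", "J0042", "variant", "modis")``) derived from one
root seed.  Streams are independent and stable: adding jurisdictions,
variants or stages never perturbs draws in existing streams.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "substream_seed"]


def substream_seed(root_seed: int, *names: object) -> int:
    """Derive a 31-bit seed for the stream addressed by ``names``.

    Kept below 2**31 so it can be handed to any library that expects a
    plain non-negative C-int seed.
    """
    key = repr(int(root_seed)) + "\x1f" + "\x1f".join(str(n) for n in names)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stream(root_seed: int, *names: object) -> np.random.Generator:
    """Return the generator for the named stream under ``root_seed``."""
    # Feed the full 256-bit digest as entropy; the 31-bit helper above is
    # only for libraries that cannot take a SeedSequence.
    key = repr(int(root_seed)) + "\x1f" + "\x1f".join(str(n) for n in names)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    entropy = int.from_bytes(digest, "big")
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))
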