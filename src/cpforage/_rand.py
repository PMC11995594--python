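"""Named, reproducible random substreams derived from one master seed.

Every stochastic stage draws from ``substream(master_seed, "stage-name", ...)``
so stages are independently reproducible and reordering one stage never
perturbs another.  Derived integer seeds stay below 2**31.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master_seed: int, *labels) -> int:
    """Deterministic 31-bit seed for a named substream."""
    key = ("|".join(str(x) for x in labels)).encode()
    return (int(master_seed) ^ zlib.crc32(key)) % (2**31 - 1)


def substream(master_seed: int, *labels) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *labels))
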