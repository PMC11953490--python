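"""Small shared helpers (deterministic seed derivation)."""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed"]

_TAGS = {}


def derive_seed(*parts) -> int:
    """Derive a sub-stream seed (< 2^31) from a tuple of ints/strings.

    Strings are mapped to stable integers so that independent RNG streams
    (batch order, augmentation, data generation, ...) never collide even when
    their numeric coordinates (seed, round, client) coincide.
    """
    ints = []
    for p in parts:
        if isinstance(p, str):
            ints.append(int.from_bytes(p.encode(), "little") % (2 ** 31))
        else:
            ints.append(int(p) % (2 ** 31))
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
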