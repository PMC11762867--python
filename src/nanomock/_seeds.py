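"""Stable, platform-independent derivation of child RNG seeds.

Child streams (per organism, per replicate, per dilution level) are keyed by
string labels rather than positional indices so that reordering unrelated
entries in a design never changes another entry's reads.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_SEP = b"\x1f"  # unit separator: cannot appear in the str() of our key parts


def derive_seed(*parts: object) -> int:
    """Hash a tuple of key parts down to a 64-bit integer seed.

    Deterministic across platforms and Python processes (unlike ``hash()``,
    which is salted per process).
    """
    payload = _SEP.join(str(p).encode("utf-8") for p in parts)
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:8], "little")
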