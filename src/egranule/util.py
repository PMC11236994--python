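"""Small shared helpers."""

from __future__ import annotations

import zlib

_MOD = 2**31 - 1


def derive_seed(seed: int, label: str) -> int:
    """Derive a per-stage child seed from one user-facing seed.

    Stage labels are hashed (CRC32) into distinct streams so that, e.g.,
    the read simulator for each genotype/allele gets its own reproducible
    stream from a single pipeline seed.  The result is always < 2**31.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(label.encode())) % _MOD
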