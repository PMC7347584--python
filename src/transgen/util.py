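"""Small shared helpers: deterministic sub-seeding and rounding."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal


def subseed(seed: int, *labels: object) -> int:
    """Derive a deterministic 63-bit sub-seed from a root seed and labels.

    Stable across sessions and platforms (uses blake2b, not ``hash``), so
    adding a new labelled stream never perturbs existing ones.
    """
    payload = repr((int(seed),) + tuple(str(x) for x in labels)).encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") >> 1


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (table-style rounding, not banker's)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
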