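"""Small shared helpers."""

from __future__ import annotations

import hashlib
import zlib
from pathlib import Path

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
    (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    """Roman numeral for a positive integer (peak labels: I, II, ..., X, ...)."""
    if n <= 0:
        raise ValueError(f"roman() requires a positive integer, got {n}")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def stable_text_hash(text: str) -> int:
    """Deterministic, platform-independent 32-bit hash of a string.

    Used to derive RNG sub-streams from genotype names; Python's builtin
    ``hash`` is salted per process and must not be used for this.
    """
    return zlib.crc32(text.encode("utf-8"))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
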