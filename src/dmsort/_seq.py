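"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array (A=0 ... T=3)."""
    try:
        return np.fromiter((_BASE_TO_CODE[b] for b in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"non-ACGT base {exc.args[0]!r} in sequence {seq!r}") from None


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def mismatches_upto(a: str, b: str, limit: int) -> int:
    """Count mismatches between equal-length strings, stopping once > limit."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
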