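"""Small nucleotide-string helpers shared across modules.

Sequences are plain uppercase Python strings over {A, C, G, T, N}.
Coordinates are 0-based half-open everywhere inside the package.
"""

from __future__ import annotations

ALPHABET = frozenset("ACGTN")

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_RC)[::-1]


def validate_alphabet(seq: str, *, what: str = "sequence") -> None:
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-IUPAC-core characters: {sorted(bad)}")


def circular_slice(seq: str, start: int, end: int) -> str:
    """Slice ``[start, end)`` of a circular sequence.

    ``start > end`` denotes an origin-wrapping interval; ``start == end``
    denotes the empty interval (a full-circle interval is not representable).
    """
    n = len(seq)
    if not (0 <= start <= n and 0 <= end <= n):
        raise ValueError(f"interval ({start}, {end}) outside sequence of length {n}")
    if start <= end:
        return seq[start:end]
    return seq[start:] + seq[:end]


def interval_length(start: int, end: int, n: int) -> int:
    """Length of the (possibly wrapping) half-open interval on a circle of size n."""
    if start <= end:
        return end - start
    return n - start + end
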