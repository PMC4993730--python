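"""Small sequence utilities shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
reader/writer converts to and from the 1-based inclusive convention at the
file boundary.
"""

from __future__ import annotations

#: Tag length bounds for a valid small-RNA insert (nt).
MIN_TAG_LEN = 18
MAX_TAG_LEN = 30

#: Default ligation adapters (Illumina small-RNA kit sequences).
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returns DNA letters)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Number of substitutions between equal-length strings.

    With ``limit`` set, counting aborts early once the limit is exceeded
    and ``limit + 1`` is returned.
    """
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return limit + 1
    return d


def prefix_match(seq: str, adapter: str, pos: int, k: int = 8, max_mismatch: int = 1) -> bool:
    """Does ``seq[pos:pos+k]`` match the first ``k`` adapter bases with at
    most ``max_mismatch`` substitutions?"""
    window = seq[pos : pos + k]
    if len(window) < k:
        return False
    return hamming(window, adapter[:k], max_mismatch) <= max_mismatch


def find_adapter(seq: str, adapter: str, k: int = 8, max_mismatch: int = 1) -> int:
    """Position of the first adapter occurrence in ``seq`` (−1 if absent).

    An occurrence is a match of the first ``k`` adapter bases allowing
    ``max_mismatch`` substitutions.  Exact occurrences are preferred: the
    first exact hit wins over an earlier inexact one (the exact scan is the
    fast path; the mismatch scan only runs when no exact hit exists).
    """
    key = adapter[:k]
    pos = seq.find(key)
    if pos >= 0:
        return pos
    if max_mismatch > 0:
        for p in range(len(seq) - k + 1):
            if hamming(seq[p : p + k], key, max_mismatch) <= max_mismatch:
                return p
    return -1
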