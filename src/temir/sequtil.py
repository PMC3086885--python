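"""Small nucleotide-sequence helpers shared across the package.

Sequences are plain uppercase DNA strings over {A, C, G, T, N}; RNA input
(U) is accepted everywhere and normalised to T internally.  All coordinates
are 0-based half-open unless a writer says otherwise.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

ALPHABET = "ACGT"


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(length: int, rng: np.random.Generator) -> str:
    """i.i.d. uniform A/C/G/T background sequence."""
    return "".join(rng.choice(list(ALPHABET), size=length))


def count_occurrences(needle: str, haystack: str) -> int:
    """Number of (possibly overlapping) exact occurrences."""
    if not needle:
        raise ValueError("empty pattern")
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def find_all(needle: str, haystack: str) -> list[int]:
    """Start offsets of every (possibly overlapping) exact occurrence."""
    if not needle:
        raise ValueError("empty pattern")
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def encode(seq: str) -> np.ndarray:
    """Map ACGTN -> 0..4 as an int8 array."""
    table = np.full(256, 4, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        table[ord(c)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
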