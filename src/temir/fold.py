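"""RNA secondary structure by base-pair-weighted Nussinov dynamic programming.

Downstream consumers only need the stem geometry of a hairpin (which
positions pair, and where the two arms are), not thermodynamic accuracy,
so the fold maximises a simple pair-weight objective (GC=3, AU=2, GU=1)
with a minimum hairpin loop of 3 nt.  The recurrence is exactly testable
against brute-force enumeration, unlike a full Turner model.  A hook
(``pair_table`` argument of :class:`HairpinStructure`) lets callers swap
in an external thermodynamic folder.

The O(n^3) kernel is numba-jitted when numba is importable and falls back
to pure Python otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequtil import encode, normalize

MIN_LOOP = 3

#: pair weights indexed by encoded nucleotides (A=0 C=1 G=2 T/U=3, N=4)
PAIR_WEIGHTS = np.zeros((5, 5), dtype=np.int64)
for _a, _b, _w in [("G", "C", 3), ("A", "T", 2), ("G", "T", 1)]:
    _i, _j = "ACGT".index(_a), "ACGT".index(_b)
    PAIR_WEIGHTS[_i, _j] = PAIR_WEIGHTS[_j, _i] = _w


def _nussinov_py(enc: np.ndarray, W: np.ndarray, min_loop: int) -> np.ndarray:
    n = len(enc)
    M = np.zeros((n, n), dtype=np.int64)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = M[i, j - 1]
            for k in range(i, j - min_loop):
                w = W[enc[k], enc[j]]
                if w > 0:
                    v = w
                    if k > i:
                        v += M[i, k - 1]
                    if k + 1 <= j - 1:
                        v += M[k + 1, j - 1]
                    if v > best:
                        best = v
            M[i, j] = best
    return M

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _nussinov_fast = njit(cache=False)(_nussinov_py)
except Exception:  # pragma: no cover
    _nussinov_fast = _nussinov_py


def _traceback(enc: np.ndarray, M: np.ndarray, W: np.ndarray, min_loop: int) -> np.ndarray:
    n = len(enc)
    pair = np.full(n, -1, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            w = W[enc[k], enc[j]]
            if w <= 0:
                continue
            v = w
            if k > i:
                v += M[i, k - 1]
            if k + 1 <= j - 1:
                v += M[k + 1, j - 1]
            if v == M[i, j]:
                pair[k], pair[j] = j, k
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                break
    return pair


@dataclass
class HairpinStructure:
    """A nested pairing of a hairpin sequence with its stem-arm geometry.

    ``pair_table[i]`` is the partner of position i or -1; ``arm5``/``arm3``
    are the 0-based half-open intervals of the main stem's two arms
    (the longest chain of nested pairs); ``fold_score`` is the total pair
    weight of the structure.
    """

    sequence: str
    pair_table: np.ndarray
    arm5: tuple[int, int]
    arm3: tuple[int, int]
    fold_score: int

    def partner(self, i: int, search: int = 0) -> int | None:
        """Partner of position i; optionally scan +/- ``search`` for the
        nearest paired neighbour when i itself is unpaired."""
        for d in sorted(range(-search, search + 1), key=abs):
            k = i + d
            if 0 <= k < len(self.sequence) and self.pair_table[k] >= 0:
                return int(self.pair_table[k]) - d
        return None


def _stem_arms(pair_table: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]]:
    """Arms of the longest chain of nested pairs (the main stem)."""
    pairs = [(i, int(j)) for i, j in enumerate(pair_table) if j > i]
    if not pairs:
        return (0, 0), (0, 0)
    pairs.sort()
    # longest chain under strict nesting (i increasing, j decreasing)
    best_len = np.ones(len(pairs), dtype=int)
    prev = np.full(len(pairs), -1, dtype=int)
    for b in range(len(pairs)):
        for a in range(b):
            if pairs[a][0] < pairs[b][0] and pairs[b][1] < pairs[a][1]:
                if best_len[a] + 1 > best_len[b]:
                    best_len[b] = best_len[a] + 1
                    prev[b] = a
    end = int(np.argmax(best_len))
    chain = []
    while end >= 0:
        chain.append(pairs[end])
        end = prev[end]
    chain.reverse()
    outer, inner = chain[0], chain[-1]
    return (outer[0], inner[0] + 1), (inner[1], outer[1] + 1)


def fold_hairpin(sequence: str, min_len: int = 40,
                 weights: np.ndarray = PAIR_WEIGHTS,
                 min_loop: int = MIN_LOOP) -> HairpinStructure:
    """Maximum-weight nested pairing of ``sequence`` plus stem-arm geometry."""
    sequence = normalize(sequence)
    if len(sequence) < min_len:
        raise ValueError(f"sequence shorter than {min_len} nt")
    enc = np.asarray(encode(sequence), dtype=np.int64)
    W = np.asarray(weights, dtype=np.int64)
    M = _nussinov_fast(enc, W, min_loop)
    pair = _traceback(enc, M, W, min_loop)
    arm5, arm3 = _stem_arms(pair)
    return HairpinStructure(
        sequence=sequence, pair_table=pair, arm5=arm5, arm3=arm3,
        fold_score=int(M[0, len(sequence) - 1]),
    )
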