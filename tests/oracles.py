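"""Independent reference implementations used only as test oracles.

These deliberately avoid the production code paths: a hand-written
affine-gap Smith-Waterman matrix fill, an exhaustive substring-pair
enumeration for tiny inputs, and two independent formulations of the
maximum-weight nested pairing (memoized rightmost recursion and
unmemoized leftmost enumeration).
"""

from __future__ import annotations

from functools import lru_cache

NEG = -(10 ** 9)


def _sub_score(a: str, b: str, match: int, mismatch: int) -> int:
    return match if a == b and a != "N" else mismatch


def sw_best_score(query: str, subject: str, match: int = 1, mismatch: int = -3,
                  gap_open: int = 5, gap_extend: int = 2) -> int:
    """Plain affine-gap Smith-Waterman optimum (single strand)."""
    m, n = len(query), len(subject)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            diag = H[i - 1][j - 1] + _sub_score(query[i - 1], subject[j - 1], match, mismatch)
            H[i][j] = max(0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def global_affine(query: str, subject: str, match: int = 1, mismatch: int = -3,
                  gap_open: int = 5, gap_extend: int = 2) -> int:
    """Global affine alignment score (for exhaustive substring pairs)."""
    m, n = len(query), len(subject)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for j in range(1, n + 1):
        E[0][j] = -gap_open - gap_extend * j
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        F[i][0] = -gap_open - gap_extend * i
        H[i][0] = F[i][0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            diag = H[i - 1][j - 1] + _sub_score(query[i - 1], subject[j - 1], match, mismatch)
            H[i][j] = max(diag, E[i][j], F[i][j])
    return H[m][n]


def exhaustive_local_score(query: str, subject: str, **kw) -> int:
    """Brute force: max global score over every substring pair (tiny n only)."""
    best = 0
    for qs in range(len(query)):
        for qe in range(qs + 1, len(query) + 1):
            for ss in range(len(subject)):
                for se in range(ss + 1, len(subject) + 1):
                    best = max(best, global_affine(query[qs:qe], subject[ss:se], **kw))
    return best


_PAIR_W = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
           ("G", "T"): 1, ("T", "G"): 1}


def nussinov_recursive(seq: str, min_loop: int = 3) -> int:
    """Memoized recursion on the rightmost position (independent of the
    production kernel's array fill)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = rec(i, j - 1)
        for k in range(i, j - min_loop):
            w = _PAIR_W.get((seq[k], seq[j]), 0)
            if w:
                left = rec(i, k - 1) if k > i else 0
                inner = rec(k + 1, j - 1) if k + 1 <= j - 1 else 0
                best = max(best, left + inner + w)
        return best

    return rec(0, len(seq) - 1)


def nussinov_enumerate(seq: str, min_loop: int = 3) -> int:
    """Unmemoized leftmost-position enumeration of every nested structure
    (exponential; use only for very short sequences)."""

    def rec(i: int, j: int) -> int:
        if i >= j:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            w = _PAIR_W.get((seq[i], seq[k]), 0)
            if w:
                best = max(best, w + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)
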