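"""Deterministic Needleman–Wunsch pairwise alignment (numba-accelerated).

One affine-gap DP core serves three callers: global identity for
representative-set clustering, semi-global read-vs-template alignment for the
NAST-style projection (free end gaps on the template side, since a read is a
fragment of a full-length gene), and semi-global primer-vs-binding-site
re-alignment.

Scoring defaults: match +1, mismatch -1, gap open -2 (cost of the first gapped
base), gap extend -1.  Ties are broken deterministically in the traceback,
preferring diagonal, then up (gap in the second sequence), then left; among
gap-state predecessors the match state is preferred.  Non-ACGT symbols never
match anything, including themselves.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encode", "align_ops", "global_identity", "OP_DIAG", "OP_UP", "OP_LEFT"]

OP_DIAG = 0  # consume one base of a and one of b
OP_UP = 1    # consume one base of a (gap in b)
OP_LEFT = 2  # consume one base of b (gap in a)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _CODE[ord(_ch)] = _i

_EPS = 1e-9
_NEG = -1e17


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string; A,C,G,T -> 0..3, everything else -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _nw(a, b, match, mismatch, gap_open, gap_extend, free_a_ends, free_b_ends):  # pragma: no cover
    m = a.size
    n = b.size
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)  # path ends with gap in b (vertical move)
    Y = np.full((m + 1, n + 1), _NEG)  # path ends with gap in a (horizontal move)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = 0.0 if free_a_ends else gap_open + gap_extend * (i - 1)
    for j in range(1, n + 1):
        Y[0, j] = 0.0 if free_b_ends else gap_open + gap_extend * (j - 1)
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            p = M[i - 1, j - 1]
            if X[i - 1, j - 1] > p:
                p = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > p:
                p = Y[i - 1, j - 1]
            M[i, j] = p + s
            x = M[i - 1, j] + gap_open
            if X[i - 1, j] + gap_extend > x:
                x = X[i - 1, j] + gap_extend
            if Y[i - 1, j] + gap_open > x:
                x = Y[i - 1, j] + gap_open
            X[i, j] = x
            y = M[i, j - 1] + gap_open
            if Y[i, j - 1] + gap_extend > y:
                y = Y[i, j - 1] + gap_extend
            if X[i, j - 1] + gap_open > y:
                y = X[i, j - 1] + gap_open
            Y[i, j] = y

    # Endpoint: free ends let the trailing overhang of one sequence be
    # consumed for free — end at the best cell of the last row (free b) or
    # last column (free a); earliest cell on ties, match state preferred.
    end_i = m
    end_j = n
    best = M[m, n]
    if X[m, n] > best:
        best = X[m, n]
    if Y[m, n] > best:
        best = Y[m, n]
    if free_b_ends:
        for j in range(0, n):
            v = M[m, j]
            if X[m, j] > v:
                v = X[m, j]
            if v > best + _EPS:
                best = v
                end_i, end_j = m, j
    if free_a_ends:
        for i in range(0, m):
            v = M[i, n]
            if Y[i, n] > v:
                v = Y[i, n]
            if v > best + _EPS:
                best = v
                end_i, end_j = i, n

    ops = np.empty(m + n, dtype=np.int8)
    nops = 0
    for _ in range(n - end_j):
        ops[nops] = OP_LEFT
        nops += 1
    for _ in range(m - end_i):
        ops[nops] = OP_UP
        nops += 1

    i = end_i
    j = end_j
    # start state: prefer M, then the gap state whose overhang is not free
    state = 0
    v = M[i, j]
    if i == m and X[i, j] > v + _EPS:
        v = X[i, j]
        state = 1
    if j == n and Y[i, j] > v + _EPS:
        state = 2

    while i > 0 or j > 0:
        if state == 0:
            if i == 0:
                state = 2
                continue
            if j == 0:
                state = 1
                continue
            ops[nops] = OP_DIAG
            nops += 1
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            target = M[i, j] - s
            i -= 1
            j -= 1
            if M[i, j] >= target - _EPS:
                state = 0
            elif X[i, j] >= target - _EPS:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[nops] = OP_UP
            nops += 1
            cur = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                state = 0
            elif j == 0 and free_a_ends:
                state = 1
            elif M[i, j] + gap_open >= cur - _EPS:
                state = 0
            elif X[i, j] + gap_extend >= cur - _EPS:
                state = 1
            else:
                state = 2
        else:
            ops[nops] = OP_LEFT
            nops += 1
            cur = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                state = 0
            elif i == 0 and free_b_ends:
                state = 2
            elif M[i, j] + gap_open >= cur - _EPS:
                state = 0
            elif X[i, j] + gap_open >= cur - _EPS:
                state = 1
            else:
                state = 2
    return ops[:nops][::-1].copy()


def align_ops(a: str | np.ndarray, b: str | np.ndarray, *, match: float = 1.0,
              mismatch: float = -1.0, gap_open: float = -2.0,
              gap_extend: float = -1.0, free_a_ends: bool = False,
              free_b_ends: bool = False) -> np.ndarray:
    """Align ``a`` against ``b`` and return the operation string.

    Returns an int8 array over {OP_DIAG, OP_UP, OP_LEFT} that consumes all of
    ``a`` and all of ``b`` in order.  With ``free_b_ends`` the leading and
    trailing runs of OP_LEFT are cost-free (``b`` overhangs a fragment ``a``);
    ``free_a_ends`` is the symmetric option, and both together give an
    overlap alignment (unrelated tails hang off either end for free).
    """
    ac = encode(a) if isinstance(a, str) else a
    bc = encode(b) if isinstance(b, str) else b
    if ac.size == 0 and bc.size == 0:
        return np.empty(0, dtype=np.int8)
    if ac.size == 0:
        return np.full(bc.size, OP_LEFT, dtype=np.int8)
    if bc.size == 0:
        return np.full(ac.size, OP_UP, dtype=np.int8)
    return _nw(ac, bc, float(match), float(mismatch), float(gap_open),
               float(gap_extend), free_a_ends, free_b_ends)


def global_identity(a: str, b: str) -> float:
    """Global pairwise identity: matches / alignment length.

    Uses linear gap cost -2 (match +1, mismatch -1) and a true global
    alignment, the definition fixed for representative-set clustering.
    """
    ac, bc = encode(a), encode(b)
    ops = align_ops(ac, bc, gap_open=-2.0, gap_extend=-2.0, free_b_ends=False)
    if ops.size == 0:
        return 1.0
    i = j = matches = 0
    for op in ops:
        if op == OP_DIAG:
            if ac[i] == bc[j] and ac[i] < 4:
                matches += 1
            i += 1
            j += 1
        elif op == OP_UP:
            i += 1
        else:
            j += 1
    return matches / ops.size
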