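"""Affine-gap Smith-Waterman dynamic programming (numba-accelerated).

Gap convention is BLAST-like: a gap of length L costs open + extend * L, so
the first gap character is charged open + extend and each further character
extend.  Scores are integers.  ``N`` (code 4) never matches anything.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0,C=1,G=2,T=3, anything else=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@njit(cache=True)
def _sw_kernel(q, t, match, mismatch, gap_open, gap_extend):
    """Gotoh local alignment.  Returns (score, qend, tend) of the best cell.

    gap_open/gap_extend are positive costs; opening a gap costs
    gap_open + gap_extend.
    """
    n, m = q.shape[0], t.shape[0]
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.zeros(m + 1, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    open_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        diag = 0
        F = 0
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[j] - gap_extend
            eo = H[j] - open_cost
            if eo > e:
                e = eo
            E[j] = e
            f = F - gap_extend
            fo = H[j - 1] - open_cost
            if fo > f:
                f = fo
            F = f
            if qi == t[j - 1] and qi < 4:
                s = diag + match
            else:
                s = diag - mismatch
            h = s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _sw_full(q, t, match, mismatch, gap_open, gap_extend):
    """Full-matrix Gotoh with traceback.

    Returns (score, qstart, qend, tstart, tend, matches, aligned_columns),
    end coordinates exclusive, for the single best local alignment.
    """
    n, m = q.shape[0], t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.zeros((n + 1, m + 1), dtype=np.int64)
    F = np.zeros((n + 1, m + 1), dtype=np.int64)
    open_cost = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[i][j - 1] - gap_extend
            eo = H[i][j - 1] - open_cost
            if eo > e:
                e = eo
            E[i][j] = e
            f = F[i - 1][j] - gap_extend
            fo = H[i - 1][j] - open_cost
            if fo > f:
                f = fo
            F[i][j] = f
            if qi == t[j - 1] and qi < 4:
                s = H[i - 1][j - 1] + match
            else:
                s = H[i - 1][j - 1] - mismatch
            h = s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i][j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj) until a zero cell
    i, j = bi, bj
    matches = 0
    cols = 0
    state = 0  # 0 = in H, 1 = in E (gap in query), 2 = in F (gap in target)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i][j]
            if h == 0:
                break
            qi = q[i - 1]
            sub = match if (qi == t[j - 1] and qi < 4) else -mismatch
            if h == H[i - 1][j - 1] + sub:
                if qi == t[j - 1] and qi < 4:
                    matches += 1
                cols += 1
                i -= 1
                j -= 1
            elif h == E[i][j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if E[i][j] == H[i][j - 1] - open_cost:
                state = 0
            j -= 1
        else:
            cols += 1
            if F[i][j] == H[i - 1][j] - open_cost:
                state = 0
            i -= 1
    return best, i, bi, j, bj, matches, cols
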