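"""Low-level profile-to-sequence local alignment kernels.

Smith-Waterman dynamic programming of a position-specific scoring matrix
against a protein sequence with affine gap penalties.  The kernels are
numba-compiled; a small pure-Python reference implementation used to
validate them lives in the test suite.

Conventions: profile columns are DP rows, sequence positions DP columns.
A gap of length ``k`` costs ``gap_open + k * gap_extend`` (BLAST-style
existence + per-residue extension).  All scores are in bits.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .io import AMINO_ACIDS

#: index of the ambiguity letter in the 21-wide score matrices
X_INDEX = 20

_AA_TO_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_TO_INDEX["X"] = X_INDEX

_ENCODE_TABLE = np.full(128, X_INDEX, dtype=np.int8)
for _aa, _i in _AA_TO_INDEX.items():
    _ENCODE_TABLE[ord(_aa)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map an amino-acid string to integer indices (X and unknowns -> 20)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[raw]


@njit(cache=True, fastmath=True)
def sw_best_score(scores, seq, gap_open, gap_extend):
    """Best local alignment score of a profile against an encoded sequence."""
    L = scores.shape[0]
    n = seq.shape[0]
    neg = np.float32(-1e30)
    h_prev = np.zeros(n + 1, dtype=np.float32)
    e_col = np.full(n + 1, neg, dtype=np.float32)
    best = np.float32(0.0)
    for j in range(1, L + 1):
        h_cur = np.zeros(n + 1, dtype=np.float32)
        f = neg
        for i in range(1, n + 1):
            diag = h_prev[i - 1] + scores[j - 1, seq[i - 1]]
            up = h_prev[i] - gap_open - gap_extend
            if e_col[i] - gap_extend > up:
                up = e_col[i] - gap_extend
            left = h_cur[i - 1] - gap_open - gap_extend
            if f - gap_extend > left:
                left = f - gap_extend
            h = diag
            if up > h:
                h = up
            if left > h:
                h = left
            if h < 0.0:
                h = 0.0
            h_cur[i] = h
            e_col[i] = up
            f = left
            if h > best:
                best = h
        h_prev = h_cur
    return best


@njit(cache=True)
def sw_traceback(scores, seq, gap_open, gap_extend):
    """Full DP with traceback.

    Returns ``(score, col_start, col_end, pos_start, pos_end, cols, poss)``
    where coordinates are 0-based half-open on profile columns / sequence
    positions and ``cols``/``poss`` list the matched (column, position)
    pairs of the best local alignment in order.
    """
    L = scores.shape[0]
    n = seq.shape[0]
    neg = np.float32(-1e30)
    H = np.zeros((L + 1, n + 1), dtype=np.float32)
    # traceback states: 0 stop, 1 diagonal, 2 gap consuming a profile
    # column (deletion in the sequence), 3 gap consuming a residue
    state = np.zeros((L + 1, n + 1), dtype=np.uint8)
    e_from_open = np.zeros((L + 1, n + 1), dtype=np.uint8)
    f_from_open = np.zeros((L + 1, n + 1), dtype=np.uint8)
    E = np.full((L + 1, n + 1), neg, dtype=np.float32)
    F = np.full((L + 1, n + 1), neg, dtype=np.float32)
    best = np.float32(0.0)
    bj = 0
    bi = 0
    for j in range(1, L + 1):
        for i in range(1, n + 1):
            e_open = H[j - 1, i] - gap_open - gap_extend
            e_ext = E[j - 1, i] - gap_extend
            if e_open >= e_ext:
                E[j, i] = e_open
                e_from_open[j, i] = 1
            else:
                E[j, i] = e_ext
            f_open = H[j, i - 1] - gap_open - gap_extend
            f_ext = F[j, i - 1] - gap_extend
            if f_open >= f_ext:
                F[j, i] = f_open
                f_from_open[j, i] = 1
            else:
                F[j, i] = f_ext
            diag = H[j - 1, i - 1] + scores[j - 1, seq[i - 1]]
            h = diag
            s = np.uint8(1)
            if E[j, i] > h:
                h = E[j, i]
                s = np.uint8(2)
            if F[j, i] > h:
                h = F[j, i]
                s = np.uint8(3)
            if h <= 0.0:
                h = 0.0
                s = np.uint8(0)
            H[j, i] = h
            state[j, i] = s
            if h > best:
                best = h
                bj = j
                bi = i
    cols = np.empty(L + n, dtype=np.int64)
    poss = np.empty(L + n, dtype=np.int64)
    k = 0
    j = bj
    i = bi
    mode = np.uint8(0)  # 0 in H, 2 in E, 3 in F
    while j > 0 and i > 0:
        if mode == 0:
            s = state[j, i]
            if s == 0:
                break
            if s == 1:
                cols[k] = j - 1
                poss[k] = i - 1
                k += 1
                j -= 1
                i -= 1
            else:
                mode = s
        elif mode == 2:
            opened = e_from_open[j, i]
            j -= 1
            if opened:
                mode = np.uint8(0)
        else:
            opened = f_from_open[j, i]
            i -= 1
            if opened:
                mode = np.uint8(0)
    cols = cols[:k][::-1].copy()
    poss = poss[:k][::-1].copy()
    if k == 0:
        return best, 0, 0, 0, 0, cols, poss
    return best, cols[0], bj, poss[0], bi, cols, poss
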