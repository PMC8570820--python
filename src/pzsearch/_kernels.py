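"""Numba dynamic-programming kernels for local alignment.

All kernels work on int8-encoded sequences (ordinals into the substitution
score array) and use the affine gap cost ``gap_open + (L - 1) * gap_extend``
for a gap of length L.

Path codes emitted by traceback: 0 = aligned column (M), 1 = column consuming
the query only (gap in subject, I), 2 = column consuming the subject only
(gap in query, D).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(2**28))

M_COL = 0
I_COL = 1  # consumes query
D_COL = 2  # consumes subject


@njit(cache=True)
def sw_score(q, s, sm, gap_open, gap_extend):
    """Optimal Smith-Waterman local score, O(n) memory, no traceback."""
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros(n + 1, dtype=np.int32)
    F = np.full(n + 1, NEG, dtype=np.int32)  # vertical gaps, per column
    best = np.int32(0)
    for i in range(1, m + 1):
        qi = q[i - 1]
        diag = np.int32(0)  # H[i-1][j-1]
        E = NEG  # horizontal gap state, within-row
        for j in range(1, n + 1):
            E = max(H[j - 1] - gap_open, E - gap_extend)
            F[j] = max(H[j] - gap_open, F[j] - gap_extend)
            h = diag + sm[qi, s[j - 1]]
            if E > h:
                h = E
            if F[j] > h:
                h = F[j]
            if h < 0:
                h = np.int32(0)
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_full(q, s, sm, gap_open, gap_extend):
    """Full Smith-Waterman with traceback.

    Returns (score, q_start, q_end, s_start, s_end, path) with 0-based
    half-open coordinates.  Ties on the best cell resolve to the smallest
    (q_end, s_end); traceback prefers aligned columns, then subject-consuming
    gaps, for determinism.
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + sm[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = np.int32(0)
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    path = np.empty(m + n, dtype=np.uint8)
    plen = 0
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sm[q[i - 1], s[j - 1]]:
                path[plen] = M_COL
                plen += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            path[plen] = D_COL
            plen += 1
            if E[i, j] == H[i, j - 1] - gap_open:
                state = 0
            j -= 1
        else:
            path[plen] = I_COL
            plen += 1
            if F[i, j] == H[i - 1, j] - gap_open:
                state = 0
            i -= 1
    out = path[:plen][::-1].copy()
    return best, i, bi, j, bj, out


@njit(cache=True)
def banded_sw(q, s, center_diag, half_width, sm, gap_open, gap_extend, x_drop):
    """Banded local alignment restricted to diagonals within *half_width* of
    *center_diag* (diagonal = s_index - q_index), with traceback.

    Cells outside the band are treated as fresh local starts (score 0), so the
    reported score is a lower bound on the unbanded optimum and is at least the
    score of any gap-free alignment on the center diagonal.  Rows whose best
    in-band score has fallen more than *x_drop* below the running best, after
    the best row, terminate the scan.

    Returns (score, q_start, q_end, s_start, s_end, path).
    """
    m = q.shape[0]
    n = s.shape[0]
    W = 2 * half_width + 1
    H = np.zeros((m + 1, W), dtype=np.int32)
    E = np.full((m + 1, W), NEG, dtype=np.int32)
    F = np.full((m + 1, W), NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        jlo = i + center_diag - half_width
        if jlo < 1:
            jlo = 1
        jhi = i + center_diag + half_width
        if jhi > n:
            jhi = n
        row_best = NEG
        for j in range(jlo, jhi + 1):
            b = j - i - center_diag + half_width
            # left neighbour (i, j-1) is band index b-1 in the same row
            if b - 1 >= 0:
                e = max(H[i, b - 1] - gap_open, E[i, b - 1] - gap_extend)
            else:
                e = NEG
            # upper neighbour (i-1, j) is band index b+1 in the previous row
            if b + 1 < W:
                f = max(H[i - 1, b + 1] - gap_open, F[i - 1, b + 1] - gap_extend)
            else:
                f = NEG
            # diagonal neighbour (i-1, j-1) shares band index b
            h = H[i - 1, b] + sm[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = np.int32(0)
            H[i, b] = h
            E[i, b] = e
            F[i, b] = f
            if h > row_best:
                row_best = h
            if h > best:
                best = h
                bi = i
                bj = j
        if i > bi and row_best < best - x_drop:
            break
    # traceback
    path = np.empty(m + n, dtype=np.uint8)
    plen = 0
    i = bi
    j = bj
    state = 0
    while i > 0 and j > 0:
        b = j - i - center_diag + half_width
        if b < 0 or b >= W:
            break
        if state == 0:
            if H[i, b] == 0:
                break
            # value of cell (i-1, j-1); out-of-band treated as 0 (fresh start)
            hd = H[i - 1, b] if i - 1 >= 0 else np.int32(0)
            if H[i, b] == hd + sm[q[i - 1], s[j - 1]]:
                path[plen] = M_COL
                plen += 1
                i -= 1
                j -= 1
            elif H[i, b] == E[i, b]:
                state = 1
            else:
                state = 2
        elif state == 1:
            path[plen] = D_COL
            plen += 1
            if b - 1 >= 0 and E[i, b] == H[i, b - 1] - gap_open:
                state = 0
            j -= 1
        else:
            path[plen] = I_COL
            plen += 1
            if b + 1 < W and F[i, b] == H[i - 1, b + 1] - gap_open:
                state = 0
            i -= 1
    out = path[:plen][::-1].copy()
    return best, i, bi, j, bj, out
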