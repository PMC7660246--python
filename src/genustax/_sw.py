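"""Numba kernels for Smith–Waterman local alignment with affine gaps.

A gap of length L costs ``gap_open + L * gap_extend``.  The traceback is
deterministic: the alignment ends at the highest-scoring cell (smallest
row, then column, on ties) and prefers diagonal over up over left moves.
Sequences are pre-encoded as small integer codes; the substitution matrix
is a dense float32 array over those codes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.float32(-1e30)


@njit(cache=True, fastmath=False)
def sw_score(a, b, submat, gap_open, gap_extend):
    """Optimal local alignment score (no traceback), O(len(b)) memory."""
    la, lb = a.shape[0], b.shape[0]
    open_cost = gap_open + gap_extend
    h_prev = np.zeros(lb + 1, dtype=np.float32)
    e_prev = np.full(lb + 1, NEG, dtype=np.float32)
    best = np.float32(0.0)
    for i in range(1, la + 1):
        h_cur = np.zeros(lb + 1, dtype=np.float32)
        e_cur = np.full(lb + 1, NEG, dtype=np.float32)
        f = NEG
        ai = a[i - 1]
        for j in range(1, lb + 1):
            e = max(h_prev[j] - open_cost, e_prev[j] - gap_extend)
            f = max(h_cur[j - 1] - open_cost, f - gap_extend)
            h = h_prev[j - 1] + submat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            e_cur[j] = e
            if h > best:
                best = h
        h_prev = h_cur
        e_prev = e_cur
    return best


@njit(cache=True, fastmath=False)
def sw_align(a, b, submat, gap_open, gap_extend):
    """Optimal local alignment with traceback statistics.

    Returns (score, qstart, qend, sstart, send, matches, mismatches,
    gaps, gap_opens, aligned_columns); coordinates are 0-based half-open
    on the inputs.  Score 0 means no positive-scoring alignment.
    """
    la, lb = a.shape[0], b.shape[0]
    open_cost = gap_open + gap_extend
    H = np.zeros((la + 1, lb + 1), dtype=np.float32)
    E = np.full((la + 1, lb + 1), NEG, dtype=np.float32)
    F = np.full((la + 1, lb + 1), NEG, dtype=np.float32)
    best = np.float32(0.0)
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            e = max(H[i - 1, j] - open_cost, E[i - 1, j] - gap_extend)
            f = max(H[i, j - 1] - open_cost, F[i, j - 1] - gap_extend)
            h = H[i - 1, j - 1] + submat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0, 0, 0, 0

    matches = 0
    mismatches = 0
    gaps = 0
    gap_opens = 0
    cols = 0
    i, j = bi, bj
    state = 0  # 0 = H, 1 = E (up), 2 = F (left)
    eps = np.float32(1e-4)
    while i > 0 or j > 0:
        if state == 0:
            if H[i, j] <= 0.0:
                break
            # prefer diagonal, then up, then left
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + submat[a[i - 1], b[j - 1]])) <= eps:
                cols += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif i > 0 and abs(H[i, j] - E[i, j]) <= eps:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            gaps += 1
            if abs(E[i, j] - (H[i - 1, j] - open_cost)) <= eps:
                state = 0
                gap_opens += 1
            i -= 1
        else:
            cols += 1
            gaps += 1
            if abs(F[i, j] - (H[i, j - 1] - open_cost)) <= eps:
                state = 0
                gap_opens += 1
            j -= 1
    return float(best), i, bi, j, bj, matches, mismatches, gaps, gap_opens, cols


def warm_up() -> None:
    """Trigger JIT compilation on tiny inputs."""
    a = np.array([0, 1, 2], dtype=np.int8)
    sub = np.eye(4, dtype=np.float32)
    sw_score(a, a, sub, np.float32(2.0), np.float32(1.0))
    sw_align(a, a, sub, np.float32(2.0), np.float32(1.0))
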