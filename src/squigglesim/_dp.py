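"""Numba kernels for the DTW dynamic program and backtrace.

Full (n x m) accumulated-cost matrix, absolute-difference local cost,
symmetric step set {(1,1),(1,0),(0,1)}, no band.  The matrix is retained
for the backtrace, which resolves ties deterministically: diagonal first,
then the step consuming a squiggle event (column move), then the step
consuming a gold event (row move).
"""

import numpy as np
from numba import njit


@njit(fastmath=False)
def accumulated_cost(x, y):
    n = x.shape[0]
    m = y.shape[0]
    D = np.empty((n, m), dtype=np.float64)
    D[0, 0] = abs(x[0] - y[0])
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + abs(x[0] - y[j])
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + abs(x[i] - y[0])
        xi = x[i]
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            D[i, j] = abs(xi - y[j]) + best
    return D


@njit
def backtrace(D):
    n, m = D.shape
    path = np.empty((n + m - 1, 2), dtype=np.int64)
    i = n - 1
    j = m - 1
    k = 0
    while True:
        path[k, 0] = i
        path[k, 1] = j
        k += 1
        if i == 0 and j == 0:
            break
        if i > 0 and j > 0:
            # tie-break preference: diagonal > column move > row move
            move = 0
            best = D[i - 1, j - 1]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
                move = 1
            if D[i - 1, j] < best:
                move = 2
        elif j > 0:
            move = 1
        else:
            move = 2
        if move == 0:
            i -= 1
            j -= 1
        elif move == 1:
            j -= 1
        else:
            i -= 1
    return path[:k][::-1].copy()
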