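"""Numba kernels for the two dynamic programs (sDTW and Viterbi)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def sdtw_kernel(query: np.ndarray, target: np.ndarray):
    """Subsequence DTW with free start/end in the target.

    Symmetric step pattern (diagonal/horizontal/vertical, unit weights),
    absolute-difference local cost.  Returns (cost, end_j, ptr) where ptr
    encodes the chosen predecessor per cell: 0=diag, 1=up (query advance),
    2=left (target advance), 3=start of a new match (row 0).
    """
    m = query.shape[0]
    n = target.shape[0]
    D = np.empty((m, n), dtype=np.float64)
    ptr = np.empty((m, n), dtype=np.int8)
    for j in range(n):
        D[0, j] = abs(query[0] - target[j])
        ptr[0, j] = 3
    for i in range(1, m):
        # j == 0: only vertical predecessor
        D[i, 0] = abs(query[i] - target[0]) + D[i - 1, 0]
        ptr[i, 0] = 1
        for j in range(1, n):
            c = abs(query[i] - target[j])
            best = D[i - 1, j - 1]
            p = np.int8(0)
            if D[i - 1, j] < best:
                best = D[i - 1, j]
                p = np.int8(1)
            if D[i, j - 1] < best:
                best = D[i, j - 1]
                p = np.int8(2)
            D[i, j] = c + best
            ptr[i, j] = p
    # ties on the end column resolve to the rightmost minimum, so an exact
    # subsequence match reports its full slice rather than a shrunken span
    end_j = 0
    best = D[m - 1, 0]
    for j in range(1, n):
        if D[m - 1, j] <= best:
            best = D[m - 1, j]
            end_j = j
    return best, end_j, ptr


@njit(cache=False)
def viterbi_kernel(log_emit: np.ndarray, log_trans: np.ndarray, log_start: np.ndarray):
    """Max-likelihood state path for a left-to-right HMM.

    ``log_emit`` is (T, S); ``log_trans`` (S, S); ``log_start`` (S,).
    Ties prefer the highest-index predecessor (>=), i.e. staying in the
    current state over a fresh transition, which places ambiguous boundaries
    as early as possible in the trace.
    """
    T, S = log_emit.shape
    delta = np.empty((T, S), dtype=np.float64)
    psi = np.empty((T, S), dtype=np.int8)
    for s in range(S):
        delta[0, s] = log_start[s] + log_emit[0, s]
        psi[0, s] = 0
    for t in range(1, T):
        for s in range(S):
            best = -np.inf
            arg = 0
            for r in range(S):
                v = delta[t - 1, r] + log_trans[r, s]
                if v >= best:
                    best = v
                    arg = r
            delta[t, s] = best + log_emit[t, s]
            psi[t, s] = arg
    # terminal state: argmax, ties to highest index
    best = -np.inf
    last = 0
    for s in range(S):
        if delta[T - 1, s] >= best:
            best = delta[T - 1, s]
            last = s
    path = np.empty(T, dtype=np.int8)
    path[T - 1] = last
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
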