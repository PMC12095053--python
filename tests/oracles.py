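"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's dynamic programs: the sDTW
oracle enumerates monotone warping paths recursively, the Viterbi oracle
enumerates every legal state sequence, and the BH oracle is the step-up
definition written directly.
"""

from functools import lru_cache
import itertools
import math

import numpy as np


def brute_force_sdtw_cost(query, target) -> float:
    """Minimum warped cost of the full query against any contiguous target
    subsequence, by exhaustive recursion over monotone paths with
    diagonal/horizontal/vertical unit steps and |q-t| local cost."""
    q = tuple(float(x) for x in query)
    t = tuple(float(x) for x in target)
    n, m = len(q), len(t)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        c = abs(q[i] - t[j])
        if i == n - 1:
            return c  # free end in target
        best = math.inf
        best = min(best, rec(i + 1, j))
        if j + 1 < m:
            best = min(best, rec(i, j + 1))
            best = min(best, rec(i + 1, j + 1))
        return c + best

    return min(rec(0, j0) for j0 in range(m))  # free start in target


def brute_force_viterbi(log_emit, log_trans, log_start):
    """Best log-likelihood over every legal state sequence.

    Assumes a left-to-right topology (no transition decreases the state
    index), so the legal sequences are exactly the non-decreasing tuples;
    each candidate's likelihood is accumulated term by term.
    """
    T, S = log_emit.shape
    best = -math.inf
    best_path = None
    for path in itertools.combinations_with_replacement(range(S), T):
        ll = log_start[path[0]] + log_emit[0, path[0]]
        for t in range(1, T):
            ll += log_trans[path[t - 1], path[t]] + log_emit[t, path[t]]
        if ll > best:
            best = ll
            best_path = path
    return best, best_path


def brute_force_bh(pvals):
    """Benjamini-Hochberg step-up, straight from the definition:
    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adjusted[idx] = running
    return adjusted
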