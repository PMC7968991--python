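"""Numba kernels for the Nussinov-McCaskill style ensemble engine.

All kernels work on a precomputed weight matrix W where W[i, j] > 0 iff
positions i < j may pair, with value exp(beta * pair_score).  Intervals
are half-open: Q[i, j] is the partition function of positions i..j-1,
with Q[i, i] = 1 (the empty structure).

The inside recursion conditions on the leftmost position i:

    Q[i, j] = Q[i+1, j] + sum_k W[i, k] * Q[i+1, k] * Q[k+1, j]

which parses every nested structure exactly once; the matching outside
recursion then yields exact base-pair probabilities.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_TOL = 1e-9


@njit(cache=False)
def inside_partition(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    Q = np.ones((n + 2, n + 2))
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n + 1):
            q = Q[i + 1, j]
            for k in range(i + 1, j):
                w = W[i, k]
                if w > 0.0:
                    q += w * Q[i + 1, k] * Q[k + 1, j]
            Q[i, j] = q
    return Q


@njit(cache=False)
def pair_probabilities(W: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Outside algorithm; returns upper-triangular P with P[i, j] = p(i pairs j)."""
    n = W.shape[0]
    O = np.zeros((n + 1, n + 1))
    O[0, n] = 1.0
    # G[i, m] = sum_{b=m..n} O[i, b] * Q[m, b]
    G = np.zeros((n + 1, n + 2))
    P = np.zeros((n, n))
    for i in range(0, n + 1):
        if i > 0:
            for j in range(i, n + 1):
                acc = O[i - 1, j]
                if j < n and W[i - 1, j] > 0.0:
                    acc += W[i - 1, j] * G[i - 1, j + 1]
                for a in range(0, i - 1):
                    if W[a, i - 1] > 0.0:
                        acc += O[a, j] * W[a, i - 1] * Q[a + 1, i - 1]
                O[i, j] = acc
        for m in range(n + 1, -1, -1):
            s = 0.0
            for b in range(m, n + 1):
                s += O[i, b] * Q[m, b]
            if m <= n:
                G[i, m] = s
    Z = Q[0, n]
    for i in range(n):
        for k in range(i + 1, n):
            if W[i, k] > 0.0:
                P[i, k] = W[i, k] * Q[i + 1, k] * G[i, k + 1] / Z
    return P


@njit(cache=False)
def mfe_tables(S: np.ndarray, allowed: np.ndarray):
    """Max-score DP.  Returns (M, C): best score and, among best-scoring
    structures, the minimum number of pairs, per half-open interval."""
    n = S.shape[0]
    M = np.zeros((n + 2, n + 2))
    C = np.zeros((n + 2, n + 2), dtype=np.int64)
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n + 1):
            best = M[i + 1, j]
            bc = C[i + 1, j]
            for k in range(i + 1, j):
                if allowed[i, k]:
                    s = S[i, k] + M[i + 1, k] + M[k + 1, j]
                    c = 1 + C[i + 1, k] + C[k + 1, j]
                    if s > best + _TOL or (s > best - _TOL and c < bc):
                        best = s
                        bc = c
            M[i, j] = best
            C[i, j] = bc
    return M, C


def mfe_traceback(S: np.ndarray, allowed: np.ndarray, M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Deterministic traceback: among max-score / fewest-pair structures,
    returns the lexicographically smallest pair table (unpaired = -1)."""
    n = S.shape[0]
    pairs = np.full(n, -1, dtype=np.int64)
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        while i < j:
            if (
                abs(M[i, j] - M[i + 1, j]) <= _TOL
                and C[i, j] == C[i + 1, j]
            ):
                i += 1  # leaving i unpaired is optimal -> lex smallest
                continue
            placed = False
            for k in range(i + 1, j):
                if allowed[i, k]:
                    s = S[i, k] + M[i + 1, k] + M[k + 1, j]
                    c = 1 + C[i + 1, k] + C[k + 1, j]
                    if abs(s - M[i, j]) <= _TOL and c == C[i, j]:
                        pairs[i], pairs[k] = k, i
                        stack.append((k + 1, j))
                        j = k
                        i += 1
                        placed = True
                        break
            if not placed:  # numerical safety; should not happen
                i += 1
    return pairs
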