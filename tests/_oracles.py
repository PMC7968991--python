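"""Independent brute-force oracles used to validate the DP engine.

Everything here enumerates explicitly over all nested structures of a
short sequence (feasible up to ~12 nt) and is deliberately written
without reference to the package's dynamic-programming code paths.
"""
from __future__ import annotations

import math
from itertools import count
from typing import Dict, List, Optional, Tuple

import numpy as np

PAIR_SCORES = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}


def pairable(seq: str, i: int, j: int, min_loop: int, nick: Optional[int]) -> bool:
    if (seq[i], seq[j]) not in PAIR_SCORES:
        return False
    if (j - i - 1) >= min_loop:
        return True
    return nick is not None and i < nick <= j


def enumerate_structures(
    seq: str, min_loop: int = 3, nick: Optional[int] = None
) -> List[List[Tuple[int, int]]]:
    """Every nested structure (as a list of (i, j) pairs), each exactly once."""
    n = len(seq)

    def rec(i: int, j: int) -> List[List[Tuple[int, int]]]:
        # half-open [i, j); condition on the leftmost position
        if i >= j:
            return [[]]
        out = list(rec(i + 1, j))
        for k in range(i + 1, j):
            if pairable(seq, i, k, min_loop, nick):
                for left in rec(i + 1, k):
                    for right in rec(k + 1, j):
                        out.append([(i, k)] + left + right)
        return out

    return rec(0, n)


def structure_score(seq: str, pairs: List[Tuple[int, int]]) -> float:
    return sum(PAIR_SCORES[(seq[i], seq[j])] for i, j in pairs)


def structure_weight(
    seq: str,
    pairs: List[Tuple[int, int]],
    beta: float,
    nick: Optional[int],
    duplex_init_penalty: float,
) -> float:
    score = structure_score(seq, pairs)
    if nick is not None and duplex_init_penalty != 0:
        if any(i < nick <= j for i, j in pairs):
            score -= duplex_init_penalty
    return math.exp(beta * score)


def brute_partition(
    seq: str,
    beta: float,
    min_loop: int = 3,
    nick: Optional[int] = None,
    duplex_init_penalty: float = 0.0,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """(Z, symmetric pair-prob matrix, p_unpaired) by full enumeration."""
    n = len(seq)
    z = 0.0
    acc = np.zeros((n, n))
    for pairs in enumerate_structures(seq, min_loop, nick):
        w = structure_weight(seq, pairs, beta, nick, duplex_init_penalty)
        z += w
        for i, j in pairs:
            acc[i, j] += w
            acc[j, i] += w
    p = acc / z
    return z, p, 1.0 - p.sum(axis=1)


def brute_mfe(
    seq: str, min_loop: int = 3, nick: Optional[int] = None
) -> Tuple[float, np.ndarray]:
    """(best score, pair table) with the engine's published tie-break:
    max score, then fewest pairs, then lexicographically smallest pair
    table (unpaired encoded as -1)."""
    n = len(seq)
    best_key = None
    best_table = None
    for pairs in enumerate_structures(seq, min_loop, nick):
        table = np.full(n, -1, dtype=np.int64)
        for i, j in pairs:
            table[i], table[j] = j, i
        key = (-structure_score(seq, pairs), len(pairs), tuple(table))
        if best_key is None or key < best_key:
            best_key = key
            best_table = table
    return -best_key[0], best_table


def brute_defect(
    seq: str,
    target_pairs: np.ndarray,
    beta: float,
    min_loop: int = 3,
    nick: Optional[int] = None,
) -> float:
    _, p, p_un = brute_partition(seq, beta, min_loop, nick)
    n = len(seq)
    d = 0.0
    for i in range(n):
        j = target_pairs[i]
        d += 1.0 - (p_un[i] if j < 0 else p[i, j])
    return d / n


def welch_formula(a, b) -> Tuple[float, float]:
    """Textbook Welch statistic and Welch-Satterthwaite df (no scipy)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
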