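"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths (and, where possible, the
libraries) they check: exact integer arithmetic for the Fisher and
hypergeometric tails, a triple loop for the topological overlap.
"""

from functools import lru_cache
from math import comb

import numpy as np


@lru_cache(maxsize=None)
def _choose(n: int, k: int) -> int:
    return comb(n, k)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact integer summation."""
    lo = max(k, 0)
    hi = min(K, n)
    num = sum(_choose(K, j) * _choose(N - K, n - j) for j in range(lo, hi + 1))
    return num / _choose(N, n)


def fisher_one_sided(nr: int, na: int, tr: int, ta: int) -> float:
    """One-sided (tumor alt-enrichment) Fisher p for the table
    [(nr, na), (tr, ta)]: the hypergeometric upper tail of ta given the
    margins."""
    N = nr + na + tr + ta
    K = na + ta  # total alt reads
    n = tr + ta  # tumor depth
    return hypergeom_upper_tail(N, K, n, ta)


def tom_triple_loop(a: np.ndarray) -> np.ndarray:
    """O(n^3) reference topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a
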