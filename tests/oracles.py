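"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (definitions, explicit
enumeration) and never calls into ripnet, so it can serve as a second,
independent route to the quantities the package computes.
"""

from itertools import product
from math import comb

import numpy as np


def modularity_of_signs(A: np.ndarray, s: np.ndarray) -> float:
    """Q of a bipartition from the definition: (1/4m) sum_ij B_ij s_i s_j."""
    k = A.sum(axis=1)
    m = k.sum() / 2.0
    B = A - np.outer(k, k) / (2.0 * m)
    return float(s @ B @ s) / (4.0 * m)


def modularity_of_labels(A: np.ndarray, labels: np.ndarray) -> float:
    """Q of an arbitrary partition by explicit double loop over node pairs."""
    k = A.sum(axis=1)
    m = k.sum() / 2.0
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


def best_bipartition_modularity(A: np.ndarray) -> float:
    """Exhaustive maximum of Q over every bipartition (n <= ~14)."""
    n = A.shape[0]
    signs = np.array(list(product((-1.0, 1.0), repeat=n)))
    k = A.sum(axis=1)
    m = k.sum() / 2.0
    B = A - np.outer(k, k) / (2.0 * m)
    qs = np.einsum("si,ij,sj->s", signs, B, signs) / (4.0 * m)
    return float(qs.max())


def count_walks(A: np.ndarray, i: int, j: int, length: int) -> int:
    """Number of walks of exactly `length` edges from i to j, by DFS."""
    if length == 0:
        return int(i == j)
    total = 0
    for nxt in np.flatnonzero(A[i]):
        total += count_walks(A, int(nxt), j, length - 1)
    return total


def cumulative_walks(A: np.ndarray, i: int, j: int, n: int) -> int:
    """Walks of every length 1..n from i to j."""
    return sum(count_walks(A, i, j, L) for L in range(1, n + 1))


def rand_by_enumeration(labels1, labels2) -> float:
    """Rand index by explicit enumeration of all node pairs."""
    n = len(labels1)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            same1 = labels1[i] == labels1[j]
            same2 = labels2[i] == labels2[j]
            agree += same1 == same2
    return agree / total


def hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for overlap of an N-draw with an n-of-M success set."""
    return sum(comb(n, x) * comb(M - n, N - x) for x in range(k, min(n, N) + 1)) / comb(M, N)
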