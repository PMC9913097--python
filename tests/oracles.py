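"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: average-linkage
clustering recomputes cluster distances from the original matrix by
explicit averaging over leaf pairs, and the hypergeometric tail is an
exact rational enumeration over the support.
"""

from fractions import Fraction
from math import comb

import numpy as np


def bruteforce_average_linkage_cophenetic(d: np.ndarray) -> np.ndarray:
    """Cophenetic matrix of average-linkage clustering of ``d``.

    Clusters are merged greedily at the minimal average inter-cluster
    distance, recomputed from scratch from the original matrix at every
    step (no Lance-Williams update).
    """
    n = d.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        avg, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = avg
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def hypergeom_upper_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), as an exact rational."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up executed literally from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * m / rank))
        adj[i] = running
    return adj
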