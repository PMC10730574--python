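"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid scipy's tests and the package's own code paths:
the Fisher oracle enumerates every 2x2 table with the observed margins,
the binomial oracle sums exact tail probabilities from math.comb, and the
DTW oracle minimises over explicitly enumerated monotone warping paths.
"""

from __future__ import annotations

from math import comb

import numpy as np

REL_TIE_TOL = 1e-7  # floating-point ties between point probabilities


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    denom = comb(n, c1)

    def point(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = point(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = point(x)
        if p <= p_obs * (1.0 + REL_TIE_TOL):
            total += p
    return total


def binom_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial test p at success probability 1/2."""
    if n == 0:
        return 1.0
    pmf = [comb(n, i) / 2.0 ** n for i in range(n + 1)]
    p_obs = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= p_obs * (1.0 + REL_TIE_TOL)))


def dtw_bruteforce(seq1: np.ndarray, seq2: np.ndarray) -> float:
    """Minimum cumulative Euclidean cost over all monotone warping paths."""
    seq1 = np.atleast_2d(seq1)
    seq2 = np.atleast_2d(seq2)
    m, n = len(seq1), len(seq2)
    cost = np.linalg.norm(seq1[:, None, :] - seq2[None, :, :], axis=2)
    best = [np.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += cost[i, j]
        if acc >= best[0]:
            return
        if i == m - 1 and j == n - 1:
            best[0] = acc
            return
        if i + 1 < m:
            walk(i + 1, j, acc)
        if j + 1 < n:
            walk(i, j + 1, acc)
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]
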