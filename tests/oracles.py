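"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths: exact rational
enumeration for Fisher's exact test and the hypergeometric tail, and
explicit rank-assignment enumeration for the Wilcoxon rank-sum test.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


def fisher_two_sided_enumeration(a, b, c, d):
    """Exact rational point-probability two-sided Fisher p-value."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):  # table [[x, r1-x], [c1-x, r2-c1+x]]
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)


def hypergeom_tail_enumeration(N, K, n, k):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    total = comb(N, n)
    favourable = sum(
        comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    )
    return Fraction(favourable, total)


def wilcoxon_two_sided_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    count = 0
    total = comb(n, n1)
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total
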