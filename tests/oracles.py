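"""Brute-force enumeration oracles for the exact rank tests.

These are deliberately naive (itertools over all group labelings / sign
patterns) and independent of the subset-sum implementation they check.
Counts are exact rationals.
"""

from fractions import Fraction
from itertools import combinations, product

import numpy as np
import scipy.stats


def mwu_exact_bruteforce(x, y) -> Fraction:
    """Two-sided exact Mann-Whitney p by enumerating all labelings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)

    def min_u(rank_sum_1: float) -> float:
        u1 = rank_sum_1 - n1 * (n1 + 1) / 2.0
        return min(u1, n1 * n2 - u1)

    observed = min_u(ranks[:n1].sum())
    extreme = 0
    total = 0
    for subset in combinations(range(n1 + n2), n1):
        total += 1
        if min_u(ranks[list(subset)].sum()) <= observed + 1e-9:
            extreme += 1
    return Fraction(extreme, total)


def wilcoxon_exact_bruteforce(a, b) -> Fraction:
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return Fraction(1)
    ranks = scipy.stats.rankdata(np.abs(d))
    total_rank = ranks.sum()

    def min_w(signs) -> float:
        w_pos = sum(r for r, s in zip(ranks, signs) if s > 0)
        return min(w_pos, total_rank - w_pos)

    observed = min_w(np.sign(d))
    extreme = 0
    for signs in product((1, -1), repeat=n):
        if min_w(signs) <= observed + 1e-9:
            extreme += 1
    return Fraction(extreme, 2**n)
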