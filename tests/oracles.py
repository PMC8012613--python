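"""Independent brute-force oracles used only by the tests.

Each function recomputes a statistic from first principles (closed form,
exact enumeration with rationals, or naive quadratic algorithms) without
touching the package's implementation paths.
"""

from fractions import Fraction
from math import comb

import numpy as np


def chi2_2x2_closed_form(a, b, c, d):
    """Pearson χ² for [[a,b],[c,d]] via the textbook closed form."""
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / den


def bh_stepup_naive(p_values):
    """O(m²) Benjamini–Hochberg step-up adjusted values."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        value = min(prev, p[i] * m / rank_from_end)
        adjusted[i] = value
        prev = value
    return adjusted


def hypergeom_pmf_exact(k, K, n, N):
    """Exact hypergeometric PMF as a Fraction."""
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def hypergeom_upper_tail_exact(k, K, n, N):
    """P(X >= k) by exact enumeration of the PMF."""
    return float(sum(hypergeom_pmf_exact(j, K, n, N) for j in range(k, min(K, n) + 1)))


def fisher_two_sided_exact(table):
    """Two-sided Fisher p by full enumeration over the fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: hypergeom_pmf_exact(x, c1, r1, n) for x in range(lo, hi + 1)
    }
    observed = probs[a]
    return float(sum(p for p in probs.values() if p <= observed))
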