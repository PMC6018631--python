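"""Exact rational-arithmetic hypergeometric oracle, independent of scipy.

Everything here works in integer/Fraction arithmetic over binomial
coefficients, so oracle values are exact; tests compare the package's
floating-point path against these.
"""

from __future__ import annotations

import math
from fractions import Fraction


def exact_pmf(k: int, s: int, M: int, N: int) -> Fraction:
    lo, hi = max(0, s + M - N), min(s, M)
    if not lo <= k <= hi:
        return Fraction(0)
    return Fraction(math.comb(M, k) * math.comb(N - M, s - k), math.comb(N, s))


def exact_upper_tail(k: int, s: int, M: int, N: int) -> Fraction:
    hi = min(s, M)
    num = sum(math.comb(M, j) * math.comb(N - M, s - j) for j in range(k, hi + 1))
    return Fraction(num, math.comb(N, s))


def exact_lower_tail(k: int, s: int, M: int, N: int) -> Fraction:
    lo = max(0, s + M - N)
    num = sum(math.comb(M, j) * math.comb(N - M, s - j) for j in range(lo, k + 1))
    return Fraction(num, math.comb(N, s))


def iter_tables(n_max: int, n_min: int = 1):
    """All valid (k, s, M, N) with n_min <= N <= n_max."""
    for N in range(n_min, n_max + 1):
        for s in range(N + 1):
            for M in range(N + 1):
                for k in range(max(0, s + M - N), min(s, M) + 1):
                    yield k, s, M, N
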