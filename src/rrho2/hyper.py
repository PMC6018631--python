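"""Exact hypergeometric overlap statistics.

The significance of the overlap between two selected gene sets is judged
against the hypergeometric distribution: drawing ``s`` genes from a universe
of ``N`` genes of which ``M`` are "successes" (the selection from the other
study), the number of overlapping genes ``k`` follows

    h(k; s, M, N) = C(M, k) * C(N-M, s-k) / C(N, s)

The upper tail H(k; s, M, N) = P(K >= k) (inclusive of the observed ``k``)
is the overlap p-value; it equals the one-sided Fisher exact test on the
2x2 table [[k, s-k], [M-k, N-M-s+k]].

All tails are evaluated in log space via :mod:`scipy.stats` so that maps
over tens of thousands of genes never underflow to p = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "ContingencyTable",
    "hypergeom_pmf",
    "hypergeom_tail",
    "hypergeom_tail_lower",
    "neg_log_tail",
    "neg_log_tail_lower",
    "expected_overlap",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Overlap counts (k, s, M, N) for one cutoff pair.

    k : overlapping genes between the two selections
    s : genes selected from study 1
    M : genes selected from study 2
    N : common genes in the universe
    """

    k: int
    s: int
    M: int
    N: int

    def __post_init__(self) -> None:
        k, s, M, N = self.k, self.s, self.M, self.N
        for name, v in (("k", k), ("s", s), ("M", M), ("N", N)):
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if s > N or M > N:
            raise ValueError(f"selections exceed the universe: s={s}, M={M}, N={N}")
        if k > min(s, M) or k < s + M - N:
            raise ValueError(
                f"k={k} outside the hypergeometric support "
                f"[{max(0, s + M - N)}, {min(s, M)}] for s={s}, M={M}, N={N}"
            )

    def as_2x2(self) -> list[list[int]]:
        """The Fisher 2x2 table [[k, s-k], [M-k, N-M-s+k]]."""
        k, s, M, N = self.k, self.s, self.M, self.N
        return [[k, s - k], [M - k, N - M - s + k]]


def hypergeom_pmf(table: ContingencyTable) -> float:
    """Probability h(k; s, M, N) of exactly ``k`` overlapping genes."""
    return float(hypergeom.pmf(table.k, table.N, table.M, table.s))


def hypergeom_tail(table: ContingencyTable) -> float:
    """Upper-tail overlap p-value H(k; s, M, N) = P(K >= k), inclusive."""
    return float(hypergeom.sf(table.k - 1, table.N, table.M, table.s))


def hypergeom_tail_lower(table: ContingencyTable) -> float:
    """Lower-tail (under-enrichment) p-value P(K <= k), inclusive."""
    return float(hypergeom.cdf(table.k, table.N, table.M, table.s))


def expected_overlap(s: int, M: int, N: int) -> float:
    """Expected overlap E(k) = s*M/N under random selection."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 <= s <= N and 0 <= M <= N):
        raise ValueError(f"need 0 <= s, M <= N; got s={s}, M={M}, N={N}")
    return s * M / N


def _log_factor(base: float | str) -> float:
    if base in (10, "10", 10.0):
        return math.log(10.0)
    if base in ("e", math.e):
        return 1.0
    raise ValueError(f"log base must be 10 or 'e', got {base!r}")


def neg_log_tail(k, s, M, N: int, log_base: float | str = 10) -> np.ndarray:
    """Vectorized -log_base P(K >= k); finite even for astronomically small tails."""
    k = np.asarray(k)
    out = -hypergeom.logsf(k - 1, N, np.asarray(M), np.asarray(s))
    return out / _log_factor(log_base) + 0.0  # normalize -0.0


def neg_log_tail_lower(k, s, M, N: int, log_base: float | str = 10) -> np.ndarray:
    """Vectorized -log_base P(K <= k) for the under-enrichment tail."""
    k = np.asarray(k)
    out = -hypergeom.logcdf(k, N, np.asarray(M), np.asarray(s))
    return out / _log_factor(log_base) + 0.0
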