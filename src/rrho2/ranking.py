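"""Ranked gene lists and their alignment.

Each gene carries a signed degree of differential expression (DDE),
``-log10(p) * direction``: up-regulated genes score positive, down-regulated
negative. A study's genes sorted by descending DDE form a
:class:`RankedGeneList`; the overlap maps consume an aligned
:class:`RankedGeneListPair` restricted to the common gene universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "GeneScore",
    "RankedGeneList",
    "RankedGeneListPair",
    "compute_dde",
    "align_and_rank",
    "sanitize_pvalues",
]


@dataclass(frozen=True)
class GeneScore:
    """One gene's signed significance score.

    dde is -log(p) * effect-direction; p_two_sided and direction are kept
    when the score was derived from them.
    """

    gene_id: str
    dde: float
    p_two_sided: Optional[float] = None
    direction: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


def compute_dde(p_two_sided: float, direction: int, log_base: float | str = 10) -> float:
    """Signed score -log_base(p) * direction; positive for up-regulated genes."""
    if not (0 < p_two_sided <= 1):
        raise ValueError(f"p-value must be in (0, 1], got {p_two_sided}")
    if direction not in (-1, 1):
        raise ValueError(f"direction must be -1 or +1, got {direction}")
    if log_base in (10, "10", 10.0):
        val = -math.log10(p_two_sided)
    elif log_base in ("e", math.e):
        val = -math.log(p_two_sided)
    else:
        raise ValueError(f"log base must be 10 or 'e', got {log_base!r}")
    return val * direction


@dataclass
class RankedGeneList:
    """Genes ordered by descending DDE.

    boundary_index is the position of the first entry with dde <= 0, i.e. the
    count of up-regulated genes; genes with dde exactly 0 sit on the
    down-regulated side.
    """

    entries: list[GeneScore]
    boundary_index: int = field(init=False)

    def __post_init__(self) -> None:
        dde = [e.dde for e in self.entries]
        if any(dde[i] < dde[i + 1] for i in range(len(dde) - 1)):
            raise ValueError("entries must be sorted by non-increasing dde")
        ids = [e.gene_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_ids in ranked list")
        self.boundary_index = int(sum(1 for d in dde if d > 0))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    @property
    def dde(self) -> np.ndarray:
        return np.array([e.dde for e in self.entries], dtype=float)

    def has_sign_change(self) -> bool:
        return 0 < self.boundary_index < len(self.entries)


@dataclass
class RankedGeneListPair:
    """Two ranked lists over the identical gene universe."""

    study1: RankedGeneList
    study2: RankedGeneList

    def __post_init__(self) -> None:
        if set(self.study1.gene_ids) != set(self.study2.gene_ids):
            raise ValueError("the two ranked lists must share the same gene universe")

    @property
    def n_common(self) -> int:
        return len(self.study1)

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-gene 0-based rank positions, aligned on a common gene order."""
        order1 = {g: i for i, g in enumerate(self.study1.gene_ids)}
        genes = self.study2.gene_ids
        pos1 = np.array([order1[g] for g in genes], dtype=np.int64)
        pos2 = np.arange(len(genes), dtype=np.int64)
        return pos1, pos2


def _sort_scores(scores: Iterable[GeneScore]) -> list[GeneScore]:
    # ties in dde broken lexicographically by gene_id: bit-reproducible maps
    return sorted(scores, key=lambda g: (-g.dde, g.gene_id))


def align_and_rank(
    list1: Sequence[GeneScore], list2: Sequence[GeneScore]
) -> RankedGeneListPair:
    """Restrict both collections to their common genes and rank each by DDE.

    Raises on duplicate gene ids or an empty intersection; logs how many
    genes were dropped from each side.
    """
    by_id1, by_id2 = {}, {}
    for coll, by_id in ((list1, by_id1), (list2, by_id2)):
        for g in coll:
            if g.gene_id in by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in input list")
            by_id[g.gene_id] = g
    common = set(by_id1) & set(by_id2)
    if not common:
        raise ValueError("the two gene lists share no genes")
    if len(common) < 10:
        log.warning("only %d genes in common; overlap maps will be coarse", len(common))
    d1, d2 = len(by_id1) - len(common), len(by_id2) - len(common)
    if d1 or d2:
        log.info("dropped %d genes from list 1 and %d from list 2 (not shared)", d1, d2)
    ranked1 = RankedGeneList(_sort_scores(by_id1[g] for g in common))
    ranked2 = RankedGeneList(_sort_scores(by_id2[g] for g in common))
    return RankedGeneListPair(ranked1, ranked2)


def sanitize_pvalues(
    p_values: Sequence[float] | np.ndarray, floor: Optional[float] = None
) -> np.ndarray:
    """Replace exact-zero p-values so -log(p) stays finite.

    Zeros become half the smallest positive value present (or ``floor`` when
    given). A sequence that is entirely zero needs an explicit floor.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    zeros = p == 0
    n_zero = int(zeros.sum())
    if n_zero == 0:
        return p.copy()
    if floor is None:
        positive = p[p > 0]
        if positive.size == 0:
            raise ValueError("all p-values are zero and no floor was configured")
        floor = float(positive.min()) / 2.0
        if floor == 0.0:  # halving underflowed at the subnormal limit
            floor = float(np.finfo(float).smallest_subnormal)
    out = p.copy()
    out[zeros] = floor
    log.info("replaced %d zero p-values with %g", n_zero, floor)
    return out
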