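"""Overlap-map construction: Enrichment, Two-sided, Stratified, Log Odds Ratio.

A map scans every pair of rank cutoffs (i, j) over two aligned ranked gene
lists and scores the overlap of the selected gene sets at each pixel.
Columns index study-1 cutoffs, rows index study-2 cutoffs; under the
rendering convention study 1's most up-regulated genes sit at the far left
and study 2's at the bottom, so the quadrants delimited by the two DDE
sign-change boundaries are

    A = up in study 1 / down in study 2   (top-left)
    B = down / down                       (top-right)
    C = up / up                           (bottom-left)
    D = down in study 1 / up in study 2   (bottom-right)

Schemes differ in where the selections are counted from:

* **enrichment** — always from the most up-regulated end of both lists;
  score = -log P(K >= k). Interpretable only in the concordant quadrants.
* **two_sided** — same counting; the score is signed by over- vs
  under-enrichment relative to E(k) = s*M/N.
* **stratified** — per quadrant, selections run from that quadrant's
  *outward* end (up end for up-sides, down end for down-sides), so all four
  quadrants carry an over-enrichment reading.
* **log_odds** — stratified selections scored by the log odds ratio of the
  2x2 overlap table instead of a tail p-value; sample-size free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

import numpy as np

from .hyper import neg_log_tail, neg_log_tail_lower
from .ranking import RankedGeneListPair

__all__ = [
    "Quadrant",
    "OverlapMap",
    "default_step_size",
    "enrichment_map",
    "two_sided_map",
    "stratified_map",
    "log_odds_map",
    "truncate_scores",
    "rescale_log_base",
]


class Quadrant(str, Enum):
    A = "A"  # up study 1 / down study 2
    B = "B"  # down / down
    C = "C"  # up / up
    D = "D"  # down study 1 / up study 2


@dataclass
class OverlapMap:
    """A pixel grid of overlap scores over the cutoff lattice.

    scores[j, i] is the score at study-1 cutoff ``cutoffs_x[i]`` and study-2
    cutoff ``cutoffs_y[j]``; counts holds the overlap size k at each pixel.
    boundary_x / boundary_y are the first column / row on the down-regulated
    side of each study's DDE sign change.
    """

    scores: np.ndarray
    counts: np.ndarray
    method: str
    log_base: str  # "10" or "e"
    boundary_x: int
    boundary_y: int
    step_size: int
    cutoffs_x: np.ndarray
    cutoffs_y: np.ndarray
    n_genes: int
    scale_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scores.shape != self.counts.shape:
            raise ValueError("scores and counts must have identical shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def quadrant_mask(self, quadrant: Quadrant | str) -> np.ndarray:
        """Boolean pixel mask of one quadrant (rows x cols)."""
        q = Quadrant(quadrant)
        n_rows, n_cols = self.scores.shape
        up_x = np.arange(n_cols) < self.boundary_x
        up_y = np.arange(n_rows) < self.boundary_y
        col = {"A": up_x, "B": ~up_x, "C": up_x, "D": ~up_x}[q.value]
        row = {"A": ~up_y, "B": ~up_y, "C": up_y, "D": up_y}[q.value]
        return row[:, None] & col[None, :]


def default_step_size(n_genes: int) -> int:
    """ceil(sqrt(N)): the customary grid spacing for rank-rank maps."""
    return int(math.ceil(math.sqrt(n_genes)))


def _normalize_base(log_base) -> str:
    if log_base in (10, "10", 10.0):
        return "10"
    if log_base in ("e", math.e):
        return "e"
    raise ValueError(f"log base must be 10 or 'e', got {log_base!r}")


def _grid(pair: RankedGeneListPair, step_size: Optional[int]):
    n = pair.n_common
    if step_size is None:
        step_size = default_step_size(n)
    if step_size < 1 or step_size >= n:
        raise ValueError(f"step_size must satisfy 1 <= step < N={n}, got {step_size}")
    cutoffs = np.arange(step_size, n + 1, step_size, dtype=np.int64)
    return step_size, cutoffs


def _cumulative_overlap(pair: RankedGeneListPair, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """K[j, i] = #{genes with study-1 rank < xs[i] and study-2 rank < ys[j]}."""
    pos1, pos2 = pair.positions()
    edges_x = np.concatenate(([-0.5], xs - 0.5))
    edges_y = np.concatenate(([-0.5], ys - 0.5))
    hist, _, _ = np.histogram2d(pos2, pos1, bins=(edges_y, edges_x))
    return np.cumsum(np.cumsum(hist, axis=0), axis=1).astype(np.int64)


def _boundary_column(cutoffs: np.ndarray, boundary_rank: int) -> int:
    """First grid index whose cutoff reaches the sign change (down side)."""
    idx = int(np.searchsorted(cutoffs, boundary_rank, side="left"))
    return min(idx, len(cutoffs) - 1)


def _boundaries(pair: RankedGeneListPair, xs: np.ndarray, ys: np.ndarray) -> tuple[int, int]:
    bx = _boundary_column(xs, pair.study1.boundary_index)
    by = _boundary_column(ys, pair.study2.boundary_index)
    return bx, by


def _stratified_counts(pair, xs, ys, bx, by):
    """Quadrant-wise outward-corner counts (k, s, M) on the full grid."""
    n = pair.n_common
    K = _cumulative_overlap(pair, xs, ys)
    X = xs[None, :].astype(np.int64)
    Y = ys[:, None].astype(np.int64)
    up_x = (np.arange(len(xs)) < bx)[None, :]
    up_y = (np.arange(len(ys)) < by)[:, None]

    s = np.where(up_x, X, n - X)
    M = np.where(up_y, Y, n - Y)
    k = np.where(
        up_x & up_y,
        K,  # C: up/up
        np.where(
            up_x & ~up_y,
            X - K,  # A: up1 with the study-2 down tail
            np.where(~up_x & up_y, Y - K, n - X - Y + K),  # D / B
        ),
    )
    return k.astype(np.int64), s, M


def _require_sign_change(pair: RankedGeneListPair, method: str) -> None:
    for name, lst in (("study 1", pair.study1), ("study 2", pair.study2)):
        if not lst.has_sign_change():
            raise ValueError(
                f"{method} map needs a DDE sign change in both lists; "
                f"{name} has all scores of one sign"
            )


def enrichment_map(
    pair: RankedGeneListPair,
    step_size: Optional[int] = None,
    log_base: float | str = 10,
) -> OverlapMap:
    """Classic rank-rank overlap map: -log P(K >= k), counting from the top.

    s = first i genes of study 1 (largest DDE), M = first j of study 2,
    k their overlap; meaningful hotspots appear only in the concordant
    quadrants B and C.
    """
    base = _normalize_base(log_base)
    step, cutoffs = _grid(pair, step_size)
    K = _cumulative_overlap(pair, cutoffs, cutoffs)
    s = cutoffs[None, :]
    M = cutoffs[:, None]
    scores = neg_log_tail(K, s, M, pair.n_common, base)
    bx, by = _boundaries(pair, cutoffs, cutoffs)
    return OverlapMap(
        scores=scores, counts=K, method="enrichment", log_base=base,
        boundary_x=bx, boundary_y=by, step_size=step,
        cutoffs_x=cutoffs, cutoffs_y=cutoffs, n_genes=pair.n_common,
    )


def two_sided_map(
    pair: RankedGeneListPair,
    step_size: Optional[int] = None,
    log_base: float | str = 10,
) -> OverlapMap:
    """Signed variant of the enrichment map.

    Positive pixels carry -log P(K >= k) (over-enrichment of same-direction
    overlap), negative pixels -(-log P(K <= k)) (under-enrichment); a pixel
    with k exactly equal to E(k) = s*M/N scores 0.
    """
    base = _normalize_base(log_base)
    step, cutoffs = _grid(pair, step_size)
    n = pair.n_common
    K = _cumulative_overlap(pair, cutoffs, cutoffs)
    s = cutoffs[None, :]
    M = cutoffs[:, None]
    expected = s * M / n
    over = neg_log_tail(K, s, M, n, base)
    under = neg_log_tail_lower(K, s, M, n, base)
    scores = np.where(K > expected, over, np.where(K < expected, -under, 0.0))
    bx, by = _boundaries(pair, cutoffs, cutoffs)
    out = OverlapMap(
        scores=scores, counts=K, method="two_sided", log_base=base,
        boundary_x=bx, boundary_y=by, step_size=step,
        cutoffs_x=cutoffs, cutoffs_y=cutoffs, n_genes=n,
    )
    return truncate_scores(out)


def stratified_map(
    pair: RankedGeneListPair,
    step_size: Optional[int] = None,
    log_base: float | str = 10,
) -> OverlapMap:
    """Quadrant-stratified overlap map.

    Every pixel belongs to exactly one quadrant; its selections are counted
    from the quadrant's outward ends, so -log P(K >= k) reads as
    over-enrichment of that quadrant's own direction pairing in all four
    quadrants.
    """
    base = _normalize_base(log_base)
    _require_sign_change(pair, "stratified")
    step, cutoffs = _grid(pair, step_size)
    bx, by = _boundaries(pair, cutoffs, cutoffs)
    k, s, M = _stratified_counts(pair, cutoffs, cutoffs, bx, by)
    scores = neg_log_tail(k, s, M, pair.n_common, base)
    return OverlapMap(
        scores=scores, counts=k, method="stratified", log_base=base,
        boundary_x=bx, boundary_y=by, step_size=step,
        cutoffs_x=cutoffs, cutoffs_y=cutoffs, n_genes=pair.n_common,
    )


def log_odds_map(
    pair: RankedGeneListPair,
    step_size: Optional[int] = None,
) -> OverlapMap:
    """Effect-size map: natural-log odds ratio of each pixel's 2x2 table.

    Selections are the stratified (outward-corner) ones, so the overlap
    odds are oriented per quadrant and theta > 0 indicates over-enrichment
    (k > E(k)) everywhere. Infinite ratios are bounded by the map's extreme
    finite values; 0/0 tables (empty selections) score 0.
    """
    _require_sign_change(pair, "log_odds")
    step, cutoffs = _grid(pair, step_size)
    bx, by = _boundaries(pair, cutoffs, cutoffs)
    n = pair.n_common
    k, s, M = _stratified_counts(pair, cutoffs, cutoffs, bx, by)
    num = k.astype(float) * (n + k - M - s)
    den = (s - k).astype(float) * (M - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.log(num) - np.log(den)
    theta[(num == 0) & (den == 0)] = 0.0
    out = OverlapMap(
        scores=theta, counts=k, method="log_odds", log_base="e",
        boundary_x=bx, boundary_y=by, step_size=step,
        cutoffs_x=cutoffs, cutoffs_y=cutoffs, n_genes=n,
    )
    return truncate_scores(out)


def truncate_scores(overlap_map: OverlapMap) -> OverlapMap:
    """Bound +/-infinite scores by the map's extreme finite values."""
    scores = overlap_map.scores
    finite = np.isfinite(scores)
    if finite.all():
        return overlap_map
    if not finite.any():
        raise ValueError("cannot truncate: every score is infinite")
    lo = float(scores[finite].min())
    hi = float(scores[finite].max())
    clipped = scores.copy()
    clipped[np.isposinf(scores)] = hi
    clipped[np.isneginf(scores)] = lo
    return replace(overlap_map, scores=clipped)


def rescale_log_base(overlap_map: OverlapMap, new_base: float | str) -> OverlapMap:
    """Convert a -log p map between base 10 and base e (rank-preserving)."""
    if overlap_map.method == "log_odds":
        raise ValueError("log-odds maps use natural log by definition; cannot rescale")
    new = _normalize_base(new_base)
    old = overlap_map.log_base
    if new == old:
        return replace(overlap_map, scores=overlap_map.scores.copy())
    factor = math.log(10.0) if (old, new) == ("10", "e") else 1.0 / math.log(10.0)
    return replace(overlap_map, scores=overlap_map.scores * factor, log_base=new)
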