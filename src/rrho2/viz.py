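"""Heatmap rendering and quadrant summaries for overlap maps.

Axis convention: study 1 runs along x with its most up-regulated genes at
the far left; study 2 runs along y with its most up-regulated genes at the
bottom. A one-cell white strip marks each study's DDE sign change, visually
separating the four quadrants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .maps import OverlapMap, Quadrant

__all__ = ["RenderSpec", "render_heatmap", "quadrant_summary"]

_SEQUENTIAL = "YlOrRd"  # white->yellow->red for pure over-enrichment scores
_DIVERGING = "RdBu_r"  # blue-white-red for signed scores


@dataclass
class RenderSpec:
    """Rendering options: color-scale caps, palette, white strip, dpi."""

    scale_max: Optional[float] = None
    scale_min: Optional[float] = None
    palette: Optional[str] = None
    white_strip: Optional[bool] = None  # default: on for stratified/log_odds
    dpi: int = 150

    def __post_init__(self) -> None:
        if (
            self.scale_min is not None
            and self.scale_max is not None
            and not self.scale_min < self.scale_max
        ):
            raise ValueError("scale_min must be below scale_max")


def _color_limits(overlap_map: OverlapMap, spec: RenderSpec):
    signed = overlap_map.method in ("two_sided", "log_odds")
    vmax = spec.scale_max
    if vmax is None:
        vmax = float(np.nanmax(np.abs(overlap_map.scores))) or 1.0
    vmin = spec.scale_min
    if vmin is None:
        vmin = -vmax if signed else 0.0
    return vmin, vmax, signed


def render_heatmap(
    overlap_map: OverlapMap, spec: Optional[RenderSpec] = None, path=None
):
    """Write the heatmap image; a TSV of the score matrix is saved alongside.

    Scores above scale_max render saturated at the cap; the underlying
    matrix is never modified. Returns the matplotlib figure.
    """
    from .io import write_map

    if overlap_map.scores.size == 0:
        raise ValueError("cannot render an empty map")
    spec = spec or RenderSpec()
    vmin, vmax, signed = _color_limits(overlap_map, spec)
    cmap_name = spec.palette or (_DIVERGING if signed else _SEQUENTIAL)
    cmap = matplotlib.colormaps[cmap_name].copy()
    cmap.set_bad("white")

    strip = spec.white_strip
    if strip is None:
        strip = overlap_map.method in ("stratified", "log_odds")
    img = np.ma.masked_invalid(overlap_map.scores.astype(float))
    if strip:
        img = img.copy()
        img[overlap_map.boundary_y, :] = np.ma.masked
        img[:, overlap_map.boundary_x] = np.ma.masked

    fig, ax = plt.subplots(figsize=(6.4, 5.6))
    mesh = ax.imshow(
        img,
        origin="lower",  # study-2 most up-regulated at the bottom
        aspect="auto",
        interpolation="nearest",
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
    )
    label = {
        "enrichment": "-log p (over-enrichment)",
        "stratified": "-log p (over-enrichment)",
        "two_sided": "signed -log p",
        "log_odds": "log odds ratio",
    }[overlap_map.method]
    fig.colorbar(mesh, ax=ax, label=label)
    ax.set_xlabel("Study 1 rank (up-regulated → down-regulated)")
    ax.set_ylabel("Study 2 rank (up-regulated → down-regulated)")
    ax.set_title(f"{overlap_map.method} overlap map")
    if path is not None:
        path = Path(path)
        fig.savefig(path, dpi=spec.dpi, bbox_inches="tight")
        write_map(overlap_map, path.with_suffix(".tsv"))
        plt.close(fig)
    return fig


def quadrant_summary(overlap_map: OverlapMap) -> pd.DataFrame:
    """Per-quadrant maximum score, its grid location, and k there.

    For enrichment/two-sided maps the quadrant partition has no stratified
    interpretation; rows then carry ``caveat=True``.
    """
    caveat = overlap_map.method in ("enrichment", "two_sided")
    rows = []
    for q in Quadrant:
        mask = overlap_map.quadrant_mask(q)
        if not mask.any():
            rows.append(
                {"quadrant": q.value, "max_score": np.nan, "cutoff_x": -1,
                 "cutoff_y": -1, "k_at_max": -1, "caveat": caveat}
            )
            continue
        scores = np.where(mask, overlap_map.scores, -np.inf)
        j, i = np.unravel_index(int(np.argmax(scores)), scores.shape)
        rows.append(
            {
                "quadrant": q.value,
                "max_score": float(overlap_map.scores[j, i]),
                "cutoff_x": int(overlap_map.cutoffs_x[i]),
                "cutoff_y": int(overlap_map.cutoffs_y[j]),
                "k_at_max": int(overlap_map.counts[j, i]),
                "caveat": caveat,
            }
        )
    return pd.DataFrame(rows)
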