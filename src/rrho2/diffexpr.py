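"""Two-group differential expression for the overlap pipeline.

A per-gene two-sample t-test (pooled variance by default, Welch optional)
yields the effect size (case mean - control mean) and a two-sided p-value;
the signed DDE score -log10(p) * sign(effect) feeds the ranking stage, and
a direction-aware one-sided p-value is emitted alongside for cross-checks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ranking import sanitize_pvalues

log = logging.getLogger(__name__)

__all__ = ["two_group_test", "one_sided_from_two_sided", "de_results_to_gene_scores"]

#: column schema of a differential-expression result table
DE_COLUMNS = ["gene_id", "effect", "p_two_sided", "p_one_sided", "dde", "degenerate"]


def one_sided_from_two_sided(
    p_two_sided: float, effect_sign: int, alternative: str = "up"
) -> float:
    """Fold a two-sided p-value into a direction-aware one-sided one.

    For the default up-regulation alternative: p/2 when the effect is
    positive, 1 - p/2 when negative, so p < 0.5 iff the effect points the
    favored way. ``alternative="down"`` swaps the convention.
    """
    if not (0 < p_two_sided <= 1):
        raise ValueError(f"p-value must be in (0, 1], got {p_two_sided}")
    if effect_sign not in (-1, 1):
        raise ValueError("effect_sign must be -1 or +1 (resolve zero effects first)")
    if alternative not in ("up", "down"):
        raise ValueError("alternative must be 'up' or 'down'")
    favored = (effect_sign == 1) == (alternative == "up")
    return p_two_sided / 2 if favored else 1 - p_two_sided / 2


def two_group_test(
    expression: np.ndarray,
    labels,
    gene_ids=None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene case-vs-control t-test on a genes x samples matrix.

    labels is a length-n_samples sequence of "case"/"control". Genes constant
    across all samples get effect 0, p 1 and a ``degenerate`` flag. Zero
    p-values from numerically infinite t statistics are floored so the DDE
    stays finite. Returns a DataFrame with columns ``DE_COLUMNS``.
    """
    X = np.asarray(expression, dtype=float)
    labels = np.asarray(labels)
    is_case = labels == "case"
    is_ctl = labels == "control"
    if not (is_case | is_ctl).all():
        bad = labels[~(is_case | is_ctl)][0]
        raise ValueError(f"labels must be 'case' or 'control', got {bad!r}")
    if is_case.sum() < 2 or is_ctl.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(X.shape[0])]

    cases, controls = X[:, is_case], X[:, is_ctl]
    effect = cases.mean(axis=1) - controls.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(cases, controls, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)

    degenerate = ~np.isfinite(p)
    if degenerate.any():
        log.info("%d genes constant across samples; p set to 1", int(degenerate.sum()))
        p[degenerate] = 1.0
        effect[degenerate] = 0.0
    p = sanitize_pvalues(p, floor=np.finfo(float).tiny)

    sign = np.sign(effect)
    with np.errstate(divide="ignore"):
        dde = -np.log10(p) * sign
    p_one = np.where(sign >= 0, p / 2, 1 - p / 2)
    p_one[sign == 0] = 0.5

    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "effect": effect,
            "p_two_sided": p,
            "p_one_sided": p_one,
            "dde": dde,
            "degenerate": degenerate,
        }
    )


def de_results_to_gene_scores(de: pd.DataFrame):
    """Convert a DE result table into ranking GeneScore records."""
    from .ranking import GeneScore

    out = []
    for row in de.itertuples(index=False):
        direction = 1 if row.effect > 0 else (-1 if row.effect < 0 else None)
        out.append(
            GeneScore(
                gene_id=str(row.gene_id),
                dde=float(row.dde),
                p_two_sided=float(row.p_two_sided),
                direction=direction,
            )
        )
    return out
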