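"""Synthetic two-study expression data with known concordant/discordant truth.

The generator emulates a two-study microarray-style experiment:

1. Per study, genes fall into correlated clusters (default 200 clusters of
   20 genes; the remaining 6,000 of 10,000 genes are independent). Each
   cluster's correlation matrix is an inverse-Wishart draw with scale
   Psi = 0.5*I + 0.5*J (df 60), standardized to unit diagonal, and the
   cluster covariance is sigma^2 * A.
2. Null expression is zero-mean Gaussian: multivariate within clusters,
   independent N(0, sigma^2) elsewhere, for 20 cases + 20 controls.
3. A subset of genes is differentially expressed: per DE gene an effect
   theta ~ N(1, 1) truncated to (0.5, inf) and a direction d ~ Bernoulli(0.5)
   are drawn; cases get the shift (-1)^d * theta added. In concordant mode
   both studies share the signed shift; in discordant mode the shift is
   flipped in study 2 only.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .diffexpr import de_results_to_gene_scores, two_group_test
from .ranking import RankedGeneListPair, align_and_rank

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedStudyPair",
    "sample_cluster_correlation",
    "simulate_null_expression",
    "inject_effects",
    "run_simulation_study",
]

_MAX_PD_RETRIES = 5


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic two-study experiment.

    Defaults are the full protocol: 10,000 genes, 200 correlated clusters of
    20, 20 cases + 20 controls per study, sigma = 1, 1,000 DE genes (10%).
    """

    n_genes: int = 10_000
    n_clusters: int = 200
    cluster_size: int = 20
    n_per_group: int = 20
    n_de: int = 1_000
    sigma: float = 1.0
    wishart_df: int = 60
    mode: str = "concordant"
    seed: Optional[int] = None
    n_studies: int = field(default=2, repr=False)

    def __post_init__(self) -> None:
        if self.n_clusters * self.cluster_size > self.n_genes:
            raise ValueError("n_clusters * cluster_size exceeds n_genes")
        if not 0 <= self.n_de <= self.n_genes:
            raise ValueError("n_de must lie in [0, n_genes]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.wishart_df <= self.cluster_size + 1:
            raise ValueError("wishart_df must exceed cluster_size + 1")
        if self.mode not in ("concordant", "discordant"):
            raise ValueError(f"mode must be concordant or discordant, got {self.mode!r}")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_studies != 2:
            raise ValueError("exactly two studies are supported")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_group


@dataclass
class SimulatedStudyPair:
    """Two expression matrices plus the generating ground truth.

    expression[s] is genes x samples for study s; theta and direction are
    defined (nonzero / 0-1) only where de_flags is True. shift[s][g] is the
    signed case-mean shift actually applied to gene g in study s.
    """

    expression: list[np.ndarray]
    group_labels: np.ndarray
    gene_ids: list[str]
    cluster_membership: np.ndarray
    de_flags: np.ndarray
    theta: np.ndarray
    direction: np.ndarray
    shift: list[np.ndarray]
    config: SimulationConfig


def sample_cluster_correlation(
    cluster_size: int, wishart_df: int, rng: np.random.Generator
) -> np.ndarray:
    """One cluster correlation matrix: standardized inverse-Wishart draw.

    Scale Psi = 0.5*I + 0.5*J; the draw A' is rescaled to unit diagonal
    (A = D^-1/2 A' D^-1/2). Draws failing a Cholesky positive-definiteness
    check are redrawn a bounded number of times.
    """
    if wishart_df <= cluster_size + 1:
        raise ValueError("wishart_df must exceed cluster_size + 1")
    if cluster_size == 1:
        # standardization forces the 1x1 matrix [1]; still consume one draw
        stats.invwishart.rvs(df=wishart_df, scale=np.ones((1, 1)), random_state=rng)
        return np.ones((1, 1))
    psi = 0.5 * np.eye(cluster_size) + 0.5 * np.ones((cluster_size, cluster_size))
    for attempt in range(_MAX_PD_RETRIES):
        raw = stats.invwishart.rvs(df=wishart_df, scale=psi, random_state=rng)
        d = np.sqrt(np.diag(raw))
        corr = raw / np.outer(d, d)
        corr = (corr + corr.T) / 2.0
        np.fill_diagonal(corr, 1.0)
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            log.warning("non-positive-definite correlation draw; retry %d", attempt + 1)
            continue
        return corr
    raise RuntimeError("failed to draw a positive-definite cluster correlation")


def simulate_null_expression(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedStudyPair:
    """Null (no-effect) expression for both studies.

    Cluster members are drawn from a correlated multivariate normal with
    covariance sigma^2 * A (A redrawn independently per cluster and per
    study); unclustered genes are independent N(0, sigma^2).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G, n_samp = config.n_genes, config.n_samples
    n_clustered = config.n_clusters * config.cluster_size

    membership = np.zeros(G, dtype=np.int64)
    clustered_genes = rng.choice(G, size=n_clustered, replace=False)
    for c in range(config.n_clusters):
        idx = clustered_genes[c * config.cluster_size : (c + 1) * config.cluster_size]
        membership[idx] = c + 1

    expression = []
    for _ in range(config.n_studies):
        X = rng.standard_normal((G, n_samp)) * config.sigma
        for c in range(config.n_clusters):
            idx = clustered_genes[c * config.cluster_size : (c + 1) * config.cluster_size]
            corr = sample_cluster_correlation(config.cluster_size, config.wishart_df, rng)
            L = np.linalg.cholesky(corr)
            z = rng.standard_normal((config.cluster_size, n_samp))
            X[idx, :] = config.sigma * (L @ z)
        expression.append(X)

    labels = np.array(["control"] * config.n_per_group + ["case"] * config.n_per_group)
    gene_ids = [f"g{i:05d}" for i in range(G)]
    return SimulatedStudyPair(
        expression=expression,
        group_labels=labels,
        gene_ids=gene_ids,
        cluster_membership=membership,
        de_flags=np.zeros(G, dtype=bool),
        theta=np.zeros(G),
        direction=np.zeros(G, dtype=np.int64),
        shift=[np.zeros(G) for _ in range(config.n_studies)],
        config=config,
    )


def _truncated_normal(
    n: int, mean: float, sd: float, lower: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling from N(mean, sd^2) truncated to (lower, inf)."""
    a = (lower - mean) / sd
    u = rng.random(n)
    cdf_a = stats.norm.cdf(a)
    return mean + sd * stats.norm.ppf(cdf_a + u * (1.0 - cdf_a))


def inject_effects(
    pair: SimulatedStudyPair,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedStudyPair:
    """Add case-only mean shifts for the DE genes, in place.

    Effect sizes theta ~ N(1,1) truncated to (0.5, inf) are shared across
    studies; directions d ~ Bernoulli(0.5) give the signed shift
    (-1)^d * theta, flipped in study 2 when mode is discordant.
    """
    if config is None:
        config = pair.config
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.n_de == 0:
        return pair
    G = config.n_genes
    de_genes = rng.choice(G, size=config.n_de, replace=False)
    theta = _truncated_normal(config.n_de, mean=1.0, sd=1.0, lower=0.5, rng=rng)
    d = rng.integers(0, 2, size=config.n_de)
    signed = ((-1.0) ** d) * theta

    is_case = pair.group_labels == "case"
    pair.de_flags[de_genes] = True
    pair.theta[de_genes] = theta
    pair.direction[de_genes] = d
    for s, X in enumerate(pair.expression):
        flip = -1.0 if (config.mode == "discordant" and s == 1) else 1.0
        pair.shift[s][de_genes] = flip * signed
        X[np.ix_(de_genes, np.where(is_case)[0])] += (flip * signed)[:, None]
    return pair


def run_simulation_study(
    config: SimulationConfig,
) -> tuple[RankedGeneListPair, SimulatedStudyPair]:
    """Full synthetic pipeline: simulate, test, rank; seed-reproducible.

    Chains null expression -> effect injection -> per-study two-group test
    -> DDE ranking, and returns the aligned ranked pair with the ground
    truth attached.
    """
    rng = np.random.default_rng(config.seed)
    pair = simulate_null_expression(config, rng)
    inject_effects(pair, config, rng)
    scores = []
    for X in pair.expression:
        de = two_group_test(X, pair.group_labels, gene_ids=pair.gene_ids)
        scores.append(de_results_to_gene_scores(de))
    ranked = align_and_rank(scores[0], scores[1])
    return ranked, pair
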