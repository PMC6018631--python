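import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rrho2 import GeneScore, align_and_rank

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_pair(dde1, dde2, genes=None):
    """Aligned ranked pair from two DDE vectors over the same genes."""
    n = len(dde1)
    if genes is None:
        genes = [f"g{i:05d}" for i in range(n)]
    l1 = [GeneScore(g, float(d)) for g, d in zip(genes, dde1)]
    l2 = [GeneScore(g, float(d)) for g, d in zip(genes, dde2)]
    return align_and_rank(l1, l2)


def signed_dde(n, rng=None):
    """n unique DDE values, half positive half negative (n even)."""
    half = n // 2
    vals = np.concatenate([np.linspace(half, 1.0, half), np.linspace(-1.0, -half, n - half)])
    if rng is not None:
        vals = rng.permutation(vals)
    return vals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def concordant_pair():
    """Identical ranked lists, half up / half down: perfect concordance."""
    dde = signed_dde(100)
    return make_pair(dde, dde)


@pytest.fixture
def discordant_pair():
    """Study 2 is study 1 with every DDE sign flipped: perfect discordance."""
    dde = signed_dde(100)
    return make_pair(dde, -dde)


@pytest.fixture
def noisy_concordant_pair():
    """Strongly rank-correlated but not identical lists (finite odds ratios)."""
    r = np.random.default_rng(77)
    dde = signed_dde(200)
    return make_pair(dde, dde + r.normal(0, 8, size=200))


@pytest.fixture
def noisy_discordant_pair():
    r = np.random.default_rng(77)
    dde = signed_dde(200)
    return make_pair(dde, -(dde + r.normal(0, 8, size=200)))
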