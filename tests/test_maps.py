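"""Map-construction schemes against the exact per-pixel oracle and by symmetry."""

import math
from dataclasses import replace

import numpy as np
import pytest

from conftest import make_pair, signed_dde
from exact_oracle import exact_upper_tail
from rrho2 import (
    enrichment_map,
    log_odds_map,
    rescale_log_base,
    stratified_map,
    truncate_scores,
    two_sided_map,
)
from rrho2.maps import Quadrant, default_step_size


def quadrant_max(overlap_map, quadrant):
    mask = overlap_map.quadrant_mask(quadrant)
    return overlap_map.scores[mask].max()


class TestEnrichmentMap:
    def test_identical_lists_overlap_completely(self, concordant_pair):
        m = enrichment_map(concordant_pair, step_size=10)
        s = m.cutoffs_x[None, :]
        M = m.cutoffs_y[:, None]
        np.testing.assert_array_equal(m.counts, np.minimum(s, M))
        j, i = np.unravel_index(np.argmax(m.scores), m.scores.shape)
        concordant = m.quadrant_mask("B") | m.quadrant_mask("C")
        assert concordant[j, i]

    def test_sign_flip_shows_no_concordant_hotspot(self, concordant_pair, discordant_pair):
        flipped = enrichment_map(discordant_pair, step_size=10)
        ident = enrichment_map(concordant_pair, step_size=10)
        assert flipped.scores.max() < ident.scores.max()
        assert flipped.scores.max() < 2.0  # nothing remotely hotspot-like

    def test_every_pixel_matches_exact_oracle(self):
        # 12-gene worked pair with hand-chosen discordance in the tails
        dde1 = [6.0, 5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0, -5.0, -6.0]
        order2 = [2, 0, 3, 1, 5, 4, 8, 6, 7, 11, 9, 10]  # study-2 rank of gene i
        dde2 = np.empty(12)
        for gene, rank in enumerate(order2):
            dde2[gene] = dde1[rank]
        pair = make_pair(dde1, dde2)
        m = enrichment_map(pair, step_size=3)
        for j, M in enumerate(m.cutoffs_y):
            for i, s in enumerate(m.cutoffs_x):
                k = int(m.counts[j, i])
                expected = -math.log10(float(exact_upper_tail(k, int(s), int(M), 12)))
                assert m.scores[j, i] == pytest.approx(expected, abs=1e-10)

    def test_symmetry_identity_when_counting_from_opposite_ends(self, rng):
        # Eq.-style mirror: same score from (k,s,M,N) and (N+k-M-s, N-s, N-M, N)
        pair = make_pair(signed_dde(60, rng), signed_dde(60, rng))
        m = enrichment_map(pair, step_size=6)
        n = pair.n_common
        for j, M in enumerate(m.cutoffs_y):
            for i, s in enumerate(m.cutoffs_x):
                k = int(m.counts[j, i])
                mirrored = float(exact_upper_tail(n + k - M - s, n - s, n - M, n))
                assert m.scores[j, i] == pytest.approx(-math.log10(mirrored), abs=1e-9)

    def test_step_size_validation(self, concordant_pair):
        with pytest.raises(ValueError):
            enrichment_map(concordant_pair, step_size=0)
        with pytest.raises(ValueError):
            enrichment_map(concordant_pair, step_size=100)

    def test_default_step_is_sqrt_n(self, concordant_pair):
        assert default_step_size(100) == 10
        m = enrichment_map(concordant_pair)
        assert m.step_size == 10

    def test_mismatched_universes_rejected(self):
        from rrho2 import GeneScore, RankedGeneList, RankedGeneListPair

        l1 = RankedGeneList([GeneScore("a", 1.0), GeneScore("b", -1.0)])
        l2 = RankedGeneList([GeneScore("a", 1.0), GeneScore("c", -1.0)])
        with pytest.raises(ValueError):
            RankedGeneListPair(l1, l2)


class TestStratifiedMap:
    def test_concordant_maxima_in_B_and_C(self, concordant_pair):
        m = stratified_map(concordant_pair, step_size=10)
        assert (m.scores >= 0).all()
        lo = max(quadrant_max(m, "A"), quadrant_max(m, "D"))
        hi = min(quadrant_max(m, "B"), quadrant_max(m, "C"))
        assert hi > lo + 5

    def test_discordant_maxima_in_A_and_D(self, discordant_pair):
        m = stratified_map(discordant_pair, step_size=10)
        lo = max(quadrant_max(m, "B"), quadrant_max(m, "C"))
        hi = min(quadrant_max(m, "A"), quadrant_max(m, "D"))
        assert hi > lo + 5

    def test_pixels_match_exact_oracle_per_quadrant(self, rng):
        pair = make_pair(signed_dde(40, rng), signed_dde(40, rng))
        m = stratified_map(pair, step_size=8)
        n = pair.n_common
        bx, by = m.boundary_x, m.boundary_y
        for j, cy in enumerate(m.cutoffs_y):
            for i, cx in enumerate(m.cutoffs_x):
                s = int(cx) if i < bx else n - int(cx)
                M = int(cy) if j < by else n - int(cy)
                k = int(m.counts[j, i])
                expected = float(exact_upper_tail(k, s, M, n))
                assert m.scores[j, i] == pytest.approx(-math.log10(expected), abs=1e-10)

    def test_one_signed_list_rejected(self):
        pair = make_pair(np.arange(1, 21, dtype=float), np.arange(1, 21, dtype=float))
        with pytest.raises(ValueError, match="sign change"):
            stratified_map(pair, step_size=4)

    def test_random_rankings_stay_far_below_concordant_signal(self, rng):
        n, reps = 1000, 50
        base = signed_dde(n)
        concordant_max = stratified_map(make_pair(base, base)).scores.max()
        null_maxima = [
            stratified_map(make_pair(rng.permutation(base), rng.permutation(base))).scores.max()
            for _ in range(reps)
        ]
        assert np.median(null_maxima) < concordant_max / 10


class TestTwoSidedMap:
    def test_positive_scores_equal_enrichment(self, concordant_pair):
        ts = two_sided_map(concordant_pair, step_size=10)
        en = enrichment_map(concordant_pair, step_size=10)
        pos = ts.scores > 0
        assert pos.any()
        np.testing.assert_allclose(ts.scores[pos], en.scores[pos], atol=1e-10)

    def test_discordant_regions_go_negative_on_sign_flip(self, discordant_pair):
        ts = two_sided_map(discordant_pair, step_size=10)
        mask_a = ts.quadrant_mask("A")
        mask_d = ts.quadrant_mask("D")
        assert ts.scores[mask_a].min() < -5
        assert ts.scores[mask_d].min() < -5

    def test_pixel_at_expected_overlap_scores_zero(self):
        # top-2 selections overlap in exactly k = s*M/N = 1 gene
        pair = make_pair([2.0, 1.0, -1.0, -2.0], [2.0, -1.0, 1.0, -2.0])
        m = two_sided_map(pair, step_size=2)
        i = list(m.cutoffs_x).index(2)
        assert m.counts[i, i] == 1
        assert m.scores[i, i] == 0.0


class TestLogOddsMap:
    def test_balanced_table_gives_zero(self):
        # direct substitution: k=2, s=4, M=5, N=10 -> log(2*3/(2*3)) = 0
        k, s, M, N = 2, 4, 5, 10
        theta = math.log((k * (N + k - M - s)) / ((s - k) * (M - k)))
        assert theta == 0.0

    def test_direct_substitution_log6(self):
        k, s, M, N = 3, 4, 5, 10
        theta = math.log((k * (N + k - M - s)) / ((s - k) * (M - k)))
        assert theta == pytest.approx(math.log(6.0), abs=1e-12)

    def test_map_scores_match_formula_and_sign_rule(self, rng):
        pair = make_pair(signed_dde(40, rng), signed_dde(40, rng))
        m = log_odds_map(pair, step_size=8)
        n = pair.n_common
        assert np.isfinite(m.scores).all()
        bx, by = m.boundary_x, m.boundary_y
        for j, cy in enumerate(m.cutoffs_y):
            for i, cx in enumerate(m.cutoffs_x):
                s = int(cx) if i < bx else n - int(cx)
                M = int(cy) if j < by else n - int(cy)
                k = int(m.counts[j, i])
                num = k * (n + k - M - s)
                den = (s - k) * (M - k)
                if num > 0 and den > 0:
                    assert m.scores[j, i] == pytest.approx(math.log(num / den), abs=1e-10)
                    # theta > 0 iff k exceeds its quadrant-specific expectation
                    assert (m.scores[j, i] > 0) == (k * n > s * M)

    def test_infinite_ratio_truncated_to_map_extremes(self, rng):
        # first/last 10 genes identical across studies -> complete-overlap
        # pixels (raw +inf) and empty-overlap pixels (raw -inf); the middle
        # is shuffled so finite scores exist to bound them
        n = 40
        dde = signed_dde(n)
        dde2 = dde.copy()
        dde2[10:30] = rng.permutation(dde2[10:30])
        m = log_odds_map(make_pair(dde, dde2), step_size=10)
        assert np.isfinite(m.scores).all()
        bx, by = m.boundary_x, m.boundary_y
        hi, lo = m.scores.max(), m.scores.min()
        saw_pos_inf = saw_neg_inf = False
        for j, cy in enumerate(m.cutoffs_y):
            for i, cx in enumerate(m.cutoffs_x):
                s = int(cx) if i < bx else n - int(cx)
                M = int(cy) if j < by else n - int(cy)
                k = int(m.counts[j, i])
                num = k * (n + k - M - s)
                den = (s - k) * (M - k)
                if num > 0 and den == 0:
                    assert m.scores[j, i] == hi
                    saw_pos_inf = True
                elif num == 0 and den > 0:
                    assert m.scores[j, i] == lo
                    saw_neg_inf = True
        assert saw_pos_inf and saw_neg_inf

    def test_concordant_and_discordant_recovery(self, noisy_concordant_pair, noisy_discordant_pair):
        m_c = log_odds_map(noisy_concordant_pair, step_size=20)
        assert min(quadrant_max(m_c, "B"), quadrant_max(m_c, "C")) > max(
            quadrant_max(m_c, "A"), quadrant_max(m_c, "D")
        )
        m_d = log_odds_map(noisy_discordant_pair, step_size=20)
        assert min(quadrant_max(m_d, "A"), quadrant_max(m_d, "D")) > max(
            quadrant_max(m_d, "B"), quadrant_max(m_d, "C")
        )


class TestTruncateAndRescale:
    def test_all_zero_map_unchanged(self, concordant_pair):
        m = enrichment_map(concordant_pair, step_size=10)
        m = replace(m, scores=np.zeros_like(m.scores))
        assert (truncate_scores(m).scores == 0).all()

    def test_infinities_clipped_to_finite_extremes(self, concordant_pair):
        m = enrichment_map(concordant_pair, step_size=10)
        m = replace(m, scores=np.array([[0.0, 3.0, np.inf], [-np.inf, -2.0, 5.0]]),
                    counts=np.zeros((2, 3), dtype=np.int64))
        out = truncate_scores(m).scores
        np.testing.assert_array_equal(out, [[0.0, 3.0, 5.0], [-2.0, -2.0, 5.0]])

    def test_all_infinite_rejected(self, concordant_pair):
        m = enrichment_map(concordant_pair, step_size=10)
        m = replace(m, scores=np.full_like(m.scores, np.inf))
        with pytest.raises(ValueError):
            truncate_scores(m)

    def test_base_change_is_multiplicative(self, concordant_pair):
        m_e = enrichment_map(concordant_pair, step_size=10, log_base="e")
        m_10 = rescale_log_base(m_e, 10)
        np.testing.assert_allclose(m_10.scores, m_e.scores / math.log(10), atol=1e-12)
        # printed claim: base-10 max is ~0.434 of the natural-log max
        assert m_10.scores.max() / m_e.scores.max() == pytest.approx(1 / math.log(10))

    def test_round_trip(self, concordant_pair):
        m = enrichment_map(concordant_pair, step_size=10)
        back = rescale_log_base(rescale_log_base(m, "e"), 10)
        np.testing.assert_allclose(back.scores, m.scores, rtol=1e-12)

    def test_log_odds_cannot_be_rescaled(self, concordant_pair):
        with pytest.raises(ValueError):
            rescale_log_base(log_odds_map(concordant_pair, step_size=10), 10)

    def test_rank_order_preserved(self, concordant_pair):
        m = enrichment_map(concordant_pair, step_size=10)
        m_e = rescale_log_base(m, "e")
        assert np.array_equal(np.argsort(m.scores, axis=None), np.argsort(m_e.scores, axis=None))
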