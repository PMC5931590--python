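"""Background-exposure estimation and knockout-signature extraction."""

import numpy as np
import pytest

from kosig.catalog import CatalogMatrix, SampleCatalog
from kosig.extract import (
    ChannelBoundaries,
    SignatureProfile,
    centroid_total_of,
    estimate_background_exposure,
    extract_knockout_signature,
    extract_signature,
    mutations_per_division,
    parental_mean_profile,
    subclone_channel_boundaries,
)
from kosig.similarity import cosine_similarity
from kosig.simulate import scenario_config, simulate_catalogs
from kosig.taxonomy import INDEL_8


def _matrix(vectors, role="subclone"):
    taxonomy = {8: "indel", 10: "rearrangement", 96: "substitution"}[len(vectors[0])]
    return CatalogMatrix(taxonomy, [
        SampleCatalog(f"s{i}", np.asarray(v), role=role)
        for i, v in enumerate(vectors)])


def _pad(vec, K=8):
    out = np.zeros(K, dtype=np.int64)
    out[: len(vec)] = vec
    return out


class TestParentalMeanProfile:
    def test_pooling(self):
        par = _matrix([_pad([4, 0]), _pad([0, 4])], role="parental")
        assert np.allclose(parental_mean_profile(par).weights[:2], [0.5, 0.5])

    def test_single_parent_identity(self):
        par = _matrix([_pad([3, 1])], role="parental")
        assert np.allclose(parental_mean_profile(par).weights[:2], [0.75, 0.25])

    def test_pooling_weights_by_totals_not_proportions(self):
        par = _matrix([_pad([9, 1]), _pad([0, 10])], role="parental")
        assert np.allclose(parental_mean_profile(par).weights[:2], [0.45, 0.55])


class TestChannelBoundaries:
    def test_one_hot_centroid_has_no_variance(self, rng):
        sub = _matrix([_pad([0, 20, 0])] * 3)
        b = subclone_channel_boundaries(sub, n_boot=500, rng=rng)
        assert b.lower[1] == b.upper[1] == 20
        assert (b.lower[[0, 2]] == 0).all() and (b.upper[[0, 2]] == 0).all()

    def test_bounds_widen_with_ci_level(self, rng):
        sub = _matrix([_pad([30, 25, 20, 15, 5, 3, 1, 1]) * 4] * 5)
        b90 = subclone_channel_boundaries(sub, n_boot=4000, ci_level=0.90,
                                          rng=np.random.default_rng(1))
        b99 = subclone_channel_boundaries(sub, n_boot=4000, ci_level=0.99,
                                          rng=np.random.default_rng(1))
        assert (b99.lower <= b90.lower).all()
        assert (b99.upper >= b90.upper).all()

    def test_per_subclone_pooling_gives_wider_or_equal_bounds(self, rng):
        cfg = scenario_config("null", "substitution", seed=31)
        _, sub, _ = simulate_catalogs(cfg, rng)
        centroid = subclone_channel_boundaries(sub, n_boot=4000,
                                               rng=np.random.default_rng(2))
        pooled = subclone_channel_boundaries(sub, n_boot=4000,
                                             rng=np.random.default_rng(2),
                                             per_subclone=True)
        # pooling across subclones adds between-sample variation
        assert (pooled.upper - pooled.lower).sum() >= \
            (centroid.upper - centroid.lower).sum()

    def test_coverage_of_true_channel_counts(self, rng):
        """~99% of fresh multinomial realizations of the centroid fall inside
        the 99% bounds, channel-wise (coverage oracle)."""
        probs = np.array([0.4, 0.3, 0.15, 0.1, 0.02, 0.02, 0.005, 0.005])
        sub = _matrix([rng.multinomial(400, probs) for _ in range(5)])
        b = subclone_channel_boundaries(sub, n_boot=6000, rng=rng)
        total = centroid_total_of(sub)
        fresh = rng.multinomial(total, sub.centroid(), size=3000)
        inside = ((fresh >= b.lower) & (fresh <= b.upper)).mean()
        assert inside > 0.97


class TestEstimateBackgroundExposure:
    def test_infinitely_wide_bounds_stop_immediately(self, rng):
        P = SignatureProfile(INDEL_8, np.full(8, 1 / 8))
        b = ChannelBoundaries(np.zeros(8), np.full(8, 10**9), 0.99)
        e_p, info = estimate_background_exposure(P, 500, b, rng=rng)
        assert e_p == 500 and info["iterations"] == 1
        assert info["acceptance_fraction"] == 1.0

    def test_null_mixture_recovers_near_total(self, rng):
        """Subclones drawn from the parental profile itself: the search stops
        within multinomial noise of the starting total."""
        cfg = scenario_config("null", "substitution", seed=8)
        par, sub, _ = simulate_catalogs(cfg, rng)
        P = parental_mean_profile(par)
        b = subclone_channel_boundaries(sub, rng=rng)
        total = centroid_total_of(sub)
        e_p, _ = estimate_background_exposure(P, total, b, rng=rng)
        assert e_p >= 0.95 * total

    def test_widening_bounds_only_increases_e_p(self, rng):
        cfg = scenario_config("msh6", "substitution", seed=2)
        par, sub, _ = simulate_catalogs(cfg, rng)
        P = parental_mean_profile(par)
        total = centroid_total_of(sub)
        narrow = subclone_channel_boundaries(sub, rng=np.random.default_rng(0))
        wide = ChannelBoundaries(narrow.lower,
                                 narrow.upper + 50, narrow.ci_level)
        e_narrow, _ = estimate_background_exposure(
            P, total, narrow, rng=np.random.default_rng(11))
        e_wide, _ = estimate_background_exposure(
            P, total, wide, rng=np.random.default_rng(11))
        assert e_wide >= e_narrow

    def test_invalid_step(self, rng):
        P = SignatureProfile(INDEL_8, np.full(8, 1 / 8))
        b = ChannelBoundaries(np.zeros(8), np.full(8, 100), 0.99)
        with pytest.raises(ValueError):
            estimate_background_exposure(P, 100, b, step=0, rng=rng)

    def test_seeded_determinism(self):
        cfg = scenario_config("msh6", "substitution", seed=5)
        par, sub, _ = simulate_catalogs(cfg)
        P = parental_mean_profile(par)
        b = subclone_channel_boundaries(sub, rng=np.random.default_rng(3))
        total = centroid_total_of(sub)
        e1, _ = estimate_background_exposure(P, total, b,
                                             rng=np.random.default_rng(7))
        e2, _ = estimate_background_exposure(P, total, b,
                                             rng=np.random.default_rng(7))
        assert e1 == e2


class TestExtractSignature:
    def test_zero_background_returns_normalized_centroid(self):
        sub = _matrix([_pad([10, 30, 0, 0])] * 2)
        P = SignatureProfile(INDEL_8, np.full(8, 1 / 8))
        res = extract_signature(sub, P, e_p=0)
        assert np.allclose(res.signature.weights[:2], [0.25, 0.75])

    def test_disjoint_supports_recover_exactly(self):
        # centroid = e_p*P_bg + e_ko*P_ko with non-overlapping supports
        P_bg = SignatureProfile(INDEL_8, _pad([1, 1, 0, 0]).astype(float))
        truth = np.zeros(8)
        truth[2:4] = [0.25, 0.75]
        counts = _pad([30, 30, 10, 30])  # e_p = 60, e_ko = 40
        sub = _matrix([counts] * 3)
        res = extract_signature(sub, P_bg, e_p=60)
        assert res.e_ko == 40
        assert np.allclose(res.signature.weights, truth, atol=1e-12)

    def test_exposure_conservation_exact(self):
        sub = _matrix([_pad([25, 25, 25, 25])] * 3)
        P = SignatureProfile(INDEL_8, np.full(8, 1 / 8))
        res = extract_signature(sub, P, e_p=37)
        assert res.e_p + res.e_ko == centroid_total_of(sub)

    def test_zero_knockout_exposure_is_error(self):
        sub = _matrix([_pad([50, 50])] * 2)
        P = SignatureProfile(INDEL_8, np.full(8, 1 / 8))
        with pytest.raises(ValueError, match="no knockout exposure"):
            extract_signature(sub, P, e_p=100)

    def test_unit_sum_and_nonnegativity_after_clipping(self, rng):
        sub = _matrix([rng.multinomial(200, np.full(8, 1 / 8))
                       for _ in range(4)])
        P = SignatureProfile(INDEL_8, np.array([0.9, 0.1, 0, 0, 0, 0, 0, 0]))
        res = extract_signature(sub, P, e_p=100)
        assert (res.signature.weights >= 0).all()
        assert abs(res.signature.weights.sum() - 1.0) < 1e-9


class TestEndToEndRecovery:
    def test_msh6_like_mixture_recovers_signature(self, rng):
        from kosig.simulate import msh6_like_substitution_profile

        cfg = scenario_config("msh6", "substitution", seed=13)
        par, sub, truth = simulate_catalogs(cfg, rng)
        res = extract_knockout_signature(sub, par, rng=rng)
        assert res.e_p + res.e_ko == centroid_total_of(sub)
        cos = cosine_similarity(res.signature.weights,
                                msh6_like_substitution_profile().weights)
        assert cos >= 0.95
        # the stop rule yields the largest compatible background, so e_p is
        # a conservative (upper) estimate of the true background exposure
        realized = truth.subclone_background_totals.mean()
        assert res.e_p >= 0.9 * realized


class TestMutationsPerDivision:
    def test_arithmetic(self):
        assert mutations_per_division(360, 36) == 10.0
        assert mutations_per_division(0, 36) == 0.0
        assert mutations_per_division(360, 18) == 20.0

    def test_invalid_divisions(self):
        with pytest.raises(ValueError):
            mutations_per_division(10, 0)
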