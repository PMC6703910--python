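"""Spearman correlation, max-statistic randomization, RF maps, RDF bins."""

import numpy as np
import pytest
from scipy import stats

from gammastruct import inference
from gammastruct.inference import (bin_by_rdf, correlate_rdf_gamma,
                                   correlation_spectra, maxstat_randomization,
                                   maxstat_spearman, rf_correlation_maps,
                                   spearman, spearman_pvalue)


def brute_force_spearman(x, y):
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_identity_and_reversal(self):
        x = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # sum of squared rank differences = 4 -> 1 - 6*4/(5*24) = 0.8
        assert spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_matches_rank_pearson_oracle(self):
        """1000 random vectors with ties agree with the oracle to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(5, 40)
            x = rng.integers(0, 8, size=n).astype(float)  # plenty of ties
            y = rng.normal(size=n).round(1)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            assert spearman(x, y) == pytest.approx(brute_force_spearman(x, y),
                                                   abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=72), rng.normal(size=72)
        r_ref, p_ref = stats.spearmanr(x, y)
        assert spearman(x, y) == pytest.approx(r_ref, abs=1e-12)
        assert spearman_pvalue(spearman(x, y), 72) == pytest.approx(p_ref,
                                                                    rel=1e-6)

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5.0))

    def test_exact_small_sample_pvalue(self):
        x = np.arange(6.0)
        p = spearman_pvalue(spearman(x, x), 6, x, x)
        assert p == pytest.approx(1 / 720 * 2, rel=1e-9)  # both perfect orders


class TestMaxstat:
    def test_constant_statistic_gives_zero_thresholds(self):
        res = maxstat_randomization(lambda labels: np.zeros((3, 4)),
                                    np.arange(20), n_rand=200, seed=0)
        assert res.upper == 0.0 and res.lower == 0.0

    def test_small_n_rand_warns(self):
        with pytest.warns(UserWarning, match="small"):
            maxstat_randomization(lambda labels: np.zeros(2), np.arange(10),
                                  n_rand=50, seed=0)

    def test_threshold_stability(self):
        """1000 vs 2000 randomizations agree within Monte-Carlo error."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=72)
        Y = rng.normal(size=(72, 50))
        _, r1 = maxstat_spearman(x, Y, n_rand=1000, seed=1)
        _, r2 = maxstat_spearman(x, Y, n_rand=2000, seed=2)
        assert abs(r1.upper - r2.upper) < 0.1 * abs(r1.upper)
        assert abs(r1.lower - r2.lower) < 0.1 * abs(r1.lower)

    def test_vectorized_and_generic_paths_agree(self):
        """maxstat_spearman matches the generic loop given the same seed."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        Y = rng.normal(size=(30, 8))
        obs, res_fast = maxstat_spearman(x, Y, n_rand=300, seed=7)

        ys = inference._ranks_std(Y)

        def stat(perm_x):
            return inference._ranks_std(perm_x) @ ys

        res_gen = maxstat_randomization(stat, x, n_rand=300, seed=7)
        assert np.allclose(obs, stat(x))
        assert np.allclose(res_fast.maxima, res_gen.maxima)

    def test_family_wise_error_calibrated(self):
        """Null simulations reject at about the nominal two-sided 2% rate."""
        rng = np.random.default_rng(4)
        n_rep, hits = 200, 0
        for rep in range(n_rep):
            x = rng.normal(size=72)
            Y = rng.normal(size=(72, 5 * 30))
            obs, res = maxstat_spearman(x, Y, n_rand=500, seed=1000 + rep)
            hits += bool(res.significant(obs).any())
        rate = hits / n_rep
        assert 0.0 <= rate < 0.06  # 95% binomial CI around 0.02 at n=200


class TestCorrelateRdfGamma:
    def test_perfect_metric(self):
        rdf = np.arange(10.0)
        r, p = correlate_rdf_gamma(rdf, rdf[None, :], rdf[None, :], "bandpower")
        assert r[0] == pytest.approx(1.0)

    def test_average_metric_is_rank_mean(self):
        rng = np.random.default_rng(5)
        h = rng.normal(size=(2, 20))
        b = rng.normal(size=(2, 20))
        avg = inference.average_rank_metric(h, b)
        expected = (stats.rankdata(h[0]) + stats.rankdata(b[0])) / 2
        assert np.allclose(avg[0], expected)

    def test_image_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            correlate_rdf_gamma(np.arange(5.0), np.zeros((1, 6)),
                                np.zeros((1, 6)), "bandpower")

    def test_positive_control_exceeds_threshold(self, session):
        """Default coupling: correlation spectra cross the max-stat bound."""
        n_sites, n_images, n_freqs = session.pc.shape
        obs, res = maxstat_spearman(
            session.rdf, session.pc.transpose(1, 0, 2).reshape(n_images, -1),
            n_rand=1000, seed=0)
        assert res.significant(obs).any()
        spec = obs.reshape(n_sites, n_freqs)
        # the correlation spectrum peaks inside the gamma band on every site
        gm = (session.stim.freqs >= 30) & (session.stim.freqs <= 80)
        for s in range(n_sites):
            assert session.stim.freqs[np.argmax(spec[s])] >= 30
            assert spec[s][gm].max() == spec[s].max()


class TestRFMaps:
    def test_shapes_and_mask(self, session, patch_rdf):
        maps, masks, res = rf_correlation_maps(patch_rdf, session.bandpower,
                                               n_rand=300, seed=0)
        assert maps.shape == (5, 19, 19)
        assert masks.dtype == bool
        assert np.all(np.abs(maps) <= 1.0)

    def test_rf_recovery_overlaps_true_disc(self, session, patch_rdf):
        """Significant patches overlap each site's true RF disc (Jaccard)."""
        from gammastruct.focus import patch_disc_mask
        maps, masks, _ = rf_correlation_maps(patch_rdf, session.bandpower,
                                             n_rand=1000, seed=0)
        for s in range(5):
            disc = patch_disc_mask(session.cfg.image_size_px,
                                   session.truth.site_rf_centers[s],
                                   session.truth.rf_radius)
            inter = (masks[s] & disc).sum()
            union = (masks[s] | disc).sum()
            assert union > 0 and inter / union > 0.2

    def test_null_session_fully_masked(self, null_session):
        from gammastruct import focus
        patch = np.stack([focus.patchwise_rdf(i) for i in null_session.images])
        maps, masks, _ = rf_correlation_maps(patch, null_session.bandpower,
                                             n_rand=1000, seed=3)
        assert not masks.any()


class TestBins:
    def test_72_images_make_8_bins_of_9(self, session):
        bins = bin_by_rdf(session.rdf, session.pc, session.stim.freqs)
        assert len(bins) == 8
        assert (bins["n_images"] == 9).all()

    def test_monotone_gamma_increase(self, session):
        """Bin-wise gamma change rises monotonically with RDF rank."""
        bins = bin_by_rdf(session.rdf, session.pc, session.stim.freqs)
        assert spearman(bins["bin"], bins["gamma_change_pct"]) >= 0.9

    def test_null_session_bins_flat(self, null_session):
        """Constant injected gamma: bin means differ only within noise."""
        bins = bin_by_rdf(null_session.rdf, null_session.pc,
                          null_session.stim.freqs)
        gm = (null_session.stim.freqs >= 30) & (null_session.stim.freqs <= 80)
        per_image = null_session.pc[:, :, gm].mean(axis=(0, 2))
        sem = per_image.std(ddof=1) / 3.0  # 9 images per bin
        spread = bins["gamma_change_pct"].std(ddof=1)
        assert spread < 2 * sem

    def test_fewer_images_than_bins_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            bin_by_rdf(np.arange(5.0), np.zeros((1, 5, 99)),
                       np.arange(4.0, 201.0, 2.0), n_bins=8)
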