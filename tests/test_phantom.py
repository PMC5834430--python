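"""Synthetic phantom: Rician sampling, averaging, SNR estimation."""

import numpy as np
import pytest

import dwidecay as dw
from dwidecay.exceptions import InvalidParameterError, UndefinedStatisticError


class TestRicianSample:
    def test_zero_noise_returns_signal_exactly(self):
        rng = np.random.default_rng(0)
        assert dw.rician_sample(3.7, 0.0, rng) == 3.7

    def test_zero_signal_has_rayleigh_mean(self):
        rng = np.random.default_rng(1)
        samples = dw.rician_sample(0.0, 2.0, rng, size=(200_000,))
        assert samples.mean() == pytest.approx(2.0 * np.sqrt(np.pi / 2),
                                               rel=5e-3)

    def test_high_snr_mean_matches_quadrature_sum(self):
        rng = np.random.default_rng(2)
        s, sigma = 20.0, 1.0
        samples = dw.rician_sample(s, sigma, rng, size=(200_000,))
        assert samples.mean() == pytest.approx(np.hypot(s, sigma), rel=5e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            dw.rician_sample(1.0, -0.1, np.random.default_rng(0))


class TestAcquireVoxel:
    def test_noise_free_acquisition_is_exact(self, scheme):
        wm = dw.default_wm_class()
        rng = np.random.default_rng(0)
        raw = dw.acquire_voxel(wm, scheme, 0.0, rng)
        expected = wm.s0_mean * np.asarray(
            dw.predict_curve("modtriexp", wm.params, scheme).s_over_s0)
        np.testing.assert_allclose(raw, expected)

    def test_doubling_nsa_shrinks_sd_by_sqrt2(self):
        # single-b schemes with nsa 4 vs 8 at the same sigma
        mk = lambda nsa: dw.BValueScheme((0.0, 1000.0), (1, nsa), 1)
        wm = dw.default_wm_class()
        rng = np.random.default_rng(3)
        lo = [dw.acquire_voxel(wm, mk(4), 1.0, rng)[1] for _ in range(4000)]
        hi = [dw.acquire_voxel(wm, mk(8), 1.0, rng)[1] for _ in range(4000)]
        ratio = np.std(lo) / np.std(hi)
        assert ratio == pytest.approx(np.sqrt(2), rel=0.05)

    def test_wm_floor_survives_at_ultra_high_b(self, scheme):
        wm = dw.default_wm_class()
        rng = np.random.default_rng(4)
        vals = [dw.acquire_voxel(wm, scheme, 1.0, rng) for _ in range(200)]
        ratios = [v[-1] / v[0] for v in vals]
        assert np.mean(ratios) > 0.1  # f0=0.15 plus Rician floor

    def test_rician_bias_positive_and_shrinking_with_averages(self):
        wm = dw.default_wm_class()
        truth = wm.s0_mean * dw.eval_modtriexp(wm.params, 8000.0)
        means = {}
        for nsa in (2, 12):
            scheme = dw.BValueScheme((0.0, 8000.0), (1, nsa), 3)
            rng = np.random.default_rng(5)
            obs = [dw.acquire_voxel(wm, scheme, 2.0, rng)[1]
                   for _ in range(3000)]
            means[nsa] = np.mean(obs)
        assert means[2] > truth and means[12] > truth
        # the averaged observation concentrates near the biased per-sample
        # mean either way, but a coarse average is noisier upward
        assert means[2] >= means[12] - 0.01


class TestMakePhantom:
    def test_fixed_seed_bit_identical(self):
        spec = dw.two_class_phantom_spec(shape=(4, 4, 1), sigma=1.0, seed=9)
        a = dw.make_phantom(spec)
        b = dw.make_phantom(spec)
        np.testing.assert_array_equal(a["data"], b["data"])

    def test_noise_free_phantom_recovers_truth(self, scheme):
        spec = dw.two_class_phantom_spec(shape=(2, 2, 1), sigma=0.0, seed=0)
        phantom = dw.make_phantom(spec)
        maps = dw.fit_volume("modtriexp", phantom["data"], scheme)
        wm_mask = phantom["labels"] == 0
        gm_mask = phantom["labels"] == 1
        assert np.allclose(maps["f0_pct"][wm_mask], 15.0, rtol=1e-3)
        assert np.allclose(maps["f0_pct"][gm_mask], 2.0, atol=0.02)
        assert np.allclose(maps["adc_slow_e6"][wm_mask], 600.0, rtol=1e-3)

    def test_truth_maps_match_class_parameters(self):
        spec = dw.two_class_phantom_spec(shape=(4, 4, 1), sigma=1.0, seed=1)
        phantom = dw.make_phantom(spec)
        wm_mask = phantom["labels"] == 0
        assert np.allclose(phantom["truth_f0"][wm_mask], 0.15)
        assert np.allclose(phantom["truth_adc_fast_e6"][wm_mask], 2000.0)

    def test_wm_f0_exceeds_gm_f0_at_study_noise(self, scheme):
        spec = dw.two_class_phantom_spec(shape=(6, 6, 1), sigma=1.0, seed=2)
        phantom = dw.make_phantom(spec)
        maps = dw.fit_volume("modtriexp", phantom["data"], scheme)
        wm_mean = np.nanmean(maps["f0_pct"][phantom["labels"] == 0])
        gm_mean = np.nanmean(maps["f0_pct"][phantom["labels"] == 1])
        assert wm_mean > gm_mean

    def test_all_magnitudes_positive(self):
        spec = dw.two_class_phantom_spec(shape=(4, 4, 2), sigma=1.0, seed=3)
        phantom = dw.make_phantom(spec)
        assert np.all(phantom["data"] > 0)


class TestSnrDifference:
    def test_recovers_known_snr(self):
        rng = np.random.default_rng(6)
        mu, sigma = 20.0, 1.0
        shape = (25, 25)  # 625-voxel ROI
        a = rng.normal(mu, sigma, shape)
        b = rng.normal(mu, sigma, shape)
        est = dw.snr_difference(a, b, np.ones(shape, dtype=bool))
        assert est.snr == pytest.approx(mu / sigma, rel=0.10)

    def test_identical_images_undefined(self):
        img = np.full((4, 4), 5.0)
        with pytest.raises(UndefinedStatisticError):
            dw.snr_difference(img, img, np.ones((4, 4), dtype=bool))

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.normal(10, 1, (20, 20))
        b = rng.normal(10, 1, (20, 20))
        roi = np.ones((20, 20), dtype=bool)
        e1 = dw.snr_difference(a, b, roi)
        e2 = dw.snr_difference(3 * a, 3 * b, roi)
        assert e2.snr == pytest.approx(e1.snr)
        assert e2.roi_mean_signal == pytest.approx(3 * e1.roi_mean_signal)


class TestNoiseToS0Ratio:
    def test_worked_example(self):
        # 18.7% remaining signal at SNR 23.7 -> noise is 0.79% of S0
        assert dw.noise_to_s0_ratio(0.187, 23.7) == pytest.approx(
            0.0079, abs=5e-5)

    def test_simple_value_and_limit(self):
        assert dw.noise_to_s0_ratio(0.5, 10) == pytest.approx(0.05)
        assert dw.noise_to_s0_ratio(0.5, 1e12) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(InvalidParameterError):
            dw.noise_to_s0_ratio(0.2, 0.0)
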