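"""Constrained voxel fitting: recovery, oracle agreement, stability."""

import numpy as np
import pytest

import dwidecay as dw
from dwidecay.exceptions import InvalidParameterError, UnfittableVoxelError
from dwidecay.fitting import DEFAULT_INIT_RANGES

from conftest import TRUE_PARAMS


class TestDefaultInit:
    def test_modtriexp_protocol_values(self):
        p = dw.default_init("modtriexp")
        assert p.f0 == 0.10 and p.f_slow == 0.50
        assert p.adc_slow == pytest.approx(600e-6)
        assert p.adc_fast == pytest.approx(2000e-6)

    def test_triexp_includes_very_slow_compartment(self):
        p = dw.default_init("triexp")
        assert p.f_very_slow == 0.10
        assert p.adc_very_slow == pytest.approx(100e-6)

    def test_biexp_is_valid(self):
        p = dw.default_init("biexp")
        assert p.f_slow == 0.50 and p.f_fast == 0.50

    def test_unknown_model_rejected(self):
        with pytest.raises(InvalidParameterError):
            dw.default_init("monoexp")


class TestNormalize:
    def test_divides_by_s0(self):
        scheme = dw.BValueScheme((0.0, 100.0, 1000.0), (1, 1, 1))
        c = dw.normalize([100.0, 50.0, 20.0], scheme)
        assert c.s_over_s0 == (1.0, 0.5, 0.2)
        assert c.s0 == 100.0

    def test_zero_s0_is_unfittable(self):
        scheme = dw.BValueScheme((0.0, 100.0, 1000.0), (1, 1, 1))
        with pytest.raises(UnfittableVoxelError):
            dw.normalize([0.0, 50.0, 20.0], scheme)

    def test_constant_signal_gives_all_ones(self):
        scheme = dw.BValueScheme((0.0, 100.0, 1000.0), (1, 1, 1))
        c = dw.normalize([7.0, 7.0, 7.0], scheme)
        assert np.allclose(c.s_over_s0, 1.0)


class TestNoiseFreeRecovery:
    @pytest.mark.parametrize("model_id", ["biexp", "triexp", "modtriexp"])
    def test_parameters_recovered_to_01_percent(self, scheme, model_id):
        truth = TRUE_PARAMS[model_id]
        curve = dw.predict_curve(model_id, truth, scheme)
        res = dw.fit_voxel(model_id, curve)
        assert res.rss < 1e-10
        assert res.n_points == 16
        for t, f in zip(truth.as_array(), res.params.as_array()):
            assert f == pytest.approx(t, rel=1e-3)

    def test_modtriexp_on_biexp_truth_drives_f0_to_zero(self, scheme):
        curve = dw.predict_curve("biexp", TRUE_PARAMS["biexp"], scheme)
        res = dw.fit_voxel("modtriexp", curve)
        assert res.params.f0 <= 1e-3

    def test_fit_result_feasible_and_ordered(self, noisy_curve_factory):
        for seed in range(5):
            curve = noisy_curve_factory(seed, noise_sd=0.02)
            for model_id in ("biexp", "triexp", "modtriexp"):
                res = dw.fit_voxel(model_id, curve)
                p = res.params  # construction re-validates all invariants
                assert p.adc_slow <= p.adc_fast
                assert 0 <= p.f_fast <= 1


class TestGridOracle:
    def test_lattice_containing_truth_hits_zero_rss(self, scheme, wm_curve):
        truth = TRUE_PARAMS["modtriexp"]
        grid = {"f0": [0.1, truth.f0, 0.2], "f_slow": [truth.f_slow],
                "adc_slow": [truth.adc_slow], "adc_fast": [truth.adc_fast]}
        res = dw.grid_oracle("modtriexp", wm_curve, grid, polish=False)
        assert res.rss < 1e-20

    def test_single_point_lattice(self, wm_curve):
        truth = TRUE_PARAMS["modtriexp"]
        grid = {"f0": [0.2], "f_slow": [0.5],
                "adc_slow": [500e-6], "adc_fast": [2500e-6]}
        res = dw.grid_oracle("modtriexp", wm_curve, grid, polish=False)
        assert res.params.f0 == pytest.approx(0.2)
        assert res.rss > 0

    def test_empty_lattice_rejected(self, wm_curve):
        with pytest.raises(InvalidParameterError):
            dw.grid_oracle("modtriexp", wm_curve, {"f0": []})

    @pytest.mark.parametrize("model_id", ["biexp", "modtriexp"])
    def test_fit_never_loses_to_oracle(self, noisy_curve_factory, model_id):
        for seed in range(8):
            curve = noisy_curve_factory(seed, noise_sd=0.01)
            fit = dw.fit_voxel(model_id, curve)
            oracle = dw.grid_oracle(model_id, curve)
            assert fit.rss <= oracle.rss + 1e-8


class TestNestedModelDominance:
    def test_richer_models_fit_at_least_as_well(self, noisy_curve_factory):
        # best-found RSS, where "best-found" includes the oracle-polished fit
        # and a fit started from the embedded poorer-model solution (the
        # nesting identities made computational)
        for seed in range(5):
            curve = noisy_curve_factory(seed, noise_sd=0.015)
            fits, best = {}, {}
            for model_id in ("biexp", "modtriexp", "triexp"):
                fits[model_id] = dw.fit_voxel(model_id, curve)
                best[model_id] = min(fits[model_id].rss,
                                     dw.grid_oracle(model_id, curve).rss)
            bi, mod = fits["biexp"].params, fits["modtriexp"].params
            embed_mod = dw.ModTriExpParams(
                f0=0.0, f_slow=bi.f_slow,
                adc_slow=bi.adc_slow, adc_fast=bi.adc_fast)
            best["modtriexp"] = min(
                best["modtriexp"],
                dw.fit_voxel("modtriexp", curve, init=embed_mod).rss)
            embed_tri = dw.TriExpParams(
                f_very_slow=mod.f0, f_slow=mod.f_slow, adc_very_slow=0.0,
                adc_slow=mod.adc_slow, adc_fast=mod.adc_fast)
            best["triexp"] = min(
                best["triexp"],
                dw.fit_voxel("triexp", curve, init=embed_tri).rss)
            assert best["modtriexp"] <= best["biexp"] + 1e-8
            assert best["triexp"] <= best["modtriexp"] + 1e-8


class TestFitVolume:
    def test_uniform_phantom_gives_constant_maps(self, scheme, wm_curve):
        raw = np.asarray(wm_curve.s_over_s0) * 100.0
        data = np.tile(raw, (2, 3, 1, 1))
        maps = dw.fit_volume("modtriexp", data, scheme)
        assert maps["f0_pct"].shape == (2, 3, 1)
        assert np.allclose(maps["f0_pct"], 15.0, atol=1e-3)
        assert np.allclose(maps["adc_fast_e6"], 2000.0, rtol=1e-4)
        assert np.all(maps["rss"] < 1e-10)

    def test_empty_mask_returns_nan_maps(self, scheme, wm_curve):
        data = np.tile(np.asarray(wm_curve.s_over_s0), (2, 2, 1, 1))
        maps = dw.fit_volume("modtriexp", data, scheme,
                             mask=np.zeros((2, 2, 1), dtype=bool))
        assert np.all(np.isnan(maps["f0_pct"]))

    def test_unfittable_voxel_is_nan(self, scheme, wm_curve):
        data = np.tile(np.asarray(wm_curve.s_over_s0), (2, 1, 1, 1))
        data[1, 0, 0, :] = 0.0  # dead voxel: S0 = 0
        maps = dw.fit_volume("modtriexp", data, scheme)
        assert np.isfinite(maps["f0_pct"][0, 0, 0])
        assert np.isnan(maps["f0_pct"][1, 0, 0])

    def test_shape_mismatch_rejected(self, scheme):
        with pytest.raises(InvalidParameterError):
            dw.fit_volume("modtriexp", np.ones((2, 2, 1, 5)), scheme)


class TestStabilityExperiment:
    def test_noise_free_curve_is_start_independent(self, wm_curve):
        df = dw.stability_experiment("modtriexp", wm_curve, n_sets=5, seed=7)
        assert len(df) == 5
        means = df[["f0", "f_slow", "adc_slow", "adc_fast"]].mean()
        sds = df[["f0", "f_slow", "adc_slow", "adc_fast"]].std()
        assert np.all(sds.to_numpy() < 1e-4 * np.abs(means.to_numpy()))

    def test_default_ranges_match_protocol(self):
        r = DEFAULT_INIT_RANGES.ranges
        assert r["f0"] == (0.05, 0.10)
        assert r["f_slow"] == (0.50, 0.60)
        assert r["adc_slow"] == (500e-6, 800e-6)
        assert r["adc_fast"] == (1900e-6, 2200e-6)

    def test_fixed_seed_reproducible(self, noisy_curve_factory):
        curve = noisy_curve_factory(3, noise_sd=0.02)
        a = dw.stability_experiment("modtriexp", curve, n_sets=4, seed=11)
        b = dw.stability_experiment("modtriexp", curve, n_sets=4, seed=11)
        assert a.equals(b)

    def test_too_few_sets_rejected(self, wm_curve):
        with pytest.raises(InvalidParameterError):
            dw.stability_experiment("modtriexp", wm_curve, n_sets=1)
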