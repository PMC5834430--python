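"""Forward-model algebra: worked values, invariants, nesting identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dwidecay as dw
from dwidecay.exceptions import InvalidParameterError

from conftest import BI_PARAMS, TRI_PARAMS, WM_PARAMS


class TestMonoAttenuation:
    @pytest.mark.parametrize("adc,b,expected", [
        (500e-6, 8000, 0.018),   # ~1.8% residual signal
        (10e-6, 8000, 0.923),    # ~92.3% residual signal
        (2000e-6, 8000, 0.000),  # fully attenuated to one decimal of %
    ])
    def test_reference_attenuations(self, adc, b, expected):
        assert dw.mono_attenuation(adc, b) == pytest.approx(expected, abs=5e-4)

    def test_no_weighting_means_no_attenuation(self):
        assert dw.mono_attenuation(1234e-6, 0.0) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            dw.mono_attenuation(-1e-6, 100)
        with pytest.raises(InvalidParameterError):
            dw.mono_attenuation(1e-6, -100)


class TestModelEvaluation:
    def test_biexp_hand_computed_value(self):
        assert dw.eval_biexp(BI_PARAMS, 1000) == pytest.approx(0.3834, abs=5e-5)

    def test_biexp_degenerates_to_mono(self):
        p = dw.BiExpParams(f_slow=1.0, adc_slow=500e-6, adc_fast=500e-6)
        assert dw.eval_biexp(p, 8000) == pytest.approx(
            dw.mono_attenuation(500e-6, 8000))

    def test_triexp_hand_computed_value(self):
        # 0.15 e^-0.1 + 0.55 e^-0.6 + 0.30 e^-2 = 0.4781726 (independent calc)
        assert dw.eval_triexp(TRI_PARAMS, 1000) == pytest.approx(
            0.4781726, abs=5e-7)

    def test_modtriexp_hand_computed_value(self):
        assert dw.eval_modtriexp(WM_PARAMS, 8000) == pytest.approx(
            0.15453, abs=5e-6)

    def test_pure_limited_compartment_never_decays(self):
        p = dw.ModTriExpParams(f0=1.0, f_slow=0.0,
                               adc_slow=600e-6, adc_fast=2000e-6)
        for b in (0, 100, 8000, 1e6):
            assert dw.eval_modtriexp(p, b) == pytest.approx(1.0)

    def test_modtriexp_asymptote_is_f0(self):
        assert dw.eval_modtriexp(WM_PARAMS, 1e9) == pytest.approx(
            WM_PARAMS.f0, rel=1e-12)

    def test_invalid_fraction_sum_rejected(self):
        with pytest.raises(InvalidParameterError):
            dw.ModTriExpParams(f0=0.6, f_slow=0.6,
                               adc_slow=600e-6, adc_fast=2000e-6)
        with pytest.raises(InvalidParameterError):
            dw.BiExpParams(f_slow=1.2, adc_slow=1e-4, adc_fast=2e-4)

    def test_adc_ordering_enforced(self):
        with pytest.raises(InvalidParameterError):
            dw.BiExpParams(f_slow=0.5, adc_slow=2e-3, adc_fast=1e-3)
        with pytest.raises(InvalidParameterError):
            dw.TriExpParams(0.1, 0.5, 5e-4, 1e-4, 2e-3)


valid_modtri = st.builds(
    dw.ModTriExpParams,
    f0=st.floats(0.0, 0.5),
    f_slow=st.floats(0.0, 0.5),
    adc_slow=st.floats(0, 1.5e-3),
    adc_fast=st.floats(1.5e-3, 5e-3),
)


class TestInvariants:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(p=valid_modtri)
    def test_unity_at_b0_and_bounded(self, p):
        b = np.array([0, 10, 100, 1000, 3000, 8000.0])
        y = dw.eval_modtriexp(p, b)
        assert y[0] == pytest.approx(1.0)
        assert np.all(y > 0) and np.all(y <= 1.0 + 1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(p=valid_modtri)
    def test_non_increasing_in_b(self, p):
        b = np.linspace(0, 8000, 40)
        y = dw.eval_modtriexp(p, b)
        assert np.all(np.diff(y) <= 1e-15)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(p=valid_modtri)
    def test_triexp_with_zero_adc_equals_modtriexp(self, p):
        tri = dw.TriExpParams(
            f_very_slow=p.f0, f_slow=p.f_slow, adc_very_slow=0.0,
            adc_slow=p.adc_slow, adc_fast=p.adc_fast)
        b = np.array([0, 50, 500, 2000, 8000.0])
        np.testing.assert_allclose(dw.eval_triexp(tri, b),
                                   dw.eval_modtriexp(p, b), rtol=0,
                                   atol=1e-15)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(f_slow=st.floats(0.0, 1.0), b=st.floats(0.0, 8000.0))
    def test_modtriexp_with_zero_f0_equals_biexp(self, f_slow, b):
        mod = dw.ModTriExpParams(f0=0.0, f_slow=f_slow,
                                 adc_slow=600e-6, adc_fast=2000e-6)
        bi = dw.BiExpParams(f_slow=f_slow, adc_slow=600e-6, adc_fast=2000e-6)
        assert dw.eval_modtriexp(mod, b) == pytest.approx(
            dw.eval_biexp(bi, b), abs=1e-15)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(f0a=st.floats(0.0, 0.4), f0b=st.floats(0.0, 0.4),
           b=st.floats(1.0, 8000.0))
    def test_signal_increases_with_f0(self, f0a, f0b, b):
        lo, hi = sorted((f0a, f0b))
        mk = lambda f0: dw.ModTriExpParams(f0=f0, f_slow=0.3,
                                           adc_slow=600e-6, adc_fast=2000e-6)
        assert dw.eval_modtriexp(mk(hi), b) >= dw.eval_modtriexp(mk(lo), b)


class TestPredictCurve:
    def test_pure_floor_gives_all_ones(self, scheme):
        p = dw.ModTriExpParams(f0=1.0, f_slow=0.0,
                               adc_slow=600e-6, adc_fast=2000e-6)
        c = dw.predict_curve("modtriexp", p, scheme)
        assert np.allclose(c.s_over_s0, 1.0)

    def test_zero_adc_biexp_gives_all_ones(self, scheme):
        p = dw.BiExpParams(f_slow=1.0, adc_slow=0.0, adc_fast=0.0)
        c = dw.predict_curve("biexp", p, scheme)
        assert np.allclose(c.s_over_s0, 1.0)

    def test_curve_consistent_with_pointwise_eval(self, scheme, wm_curve):
        assert wm_curve.value_at(8000) == pytest.approx(
            dw.eval_modtriexp(WM_PARAMS, 8000))

    def test_model_params_mismatch_rejected(self, scheme):
        with pytest.raises(InvalidParameterError):
            dw.predict_curve("biexp", WM_PARAMS, scheme)


class TestSchemeAndSerialization:
    def test_default_scheme_is_the_17_value_protocol(self, scheme):
        assert len(scheme) == 17
        assert scheme.b_values[0] == 0 and scheme.b_values[-1] == 8000
        assert scheme.nsa == (1, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 5, 5, 5, 5, 9, 12)
        assert scheme.n_directions == 3

    def test_scheme_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            dw.BValueScheme((10.0, 20.0), (1, 1))     # no b=0
        with pytest.raises(InvalidParameterError):
            dw.BValueScheme((0.0, 20.0, 20.0), (1, 1, 1))  # not increasing
        with pytest.raises(InvalidParameterError):
            dw.BValueScheme((0.0, 20.0), (1, 0))      # nsa < 1

    @pytest.mark.parametrize("params", [BI_PARAMS, TRI_PARAMS, WM_PARAMS])
    def test_params_roundtrip_through_display_units(self, params):
        d = params.to_dict()
        assert d["adc_slow_e6"] == pytest.approx(params.adc_slow * 1e6)
        back = dw.signal_models.params_from_dict(d)
        assert type(back) is type(params)
        np.testing.assert_allclose(back.as_array(), params.as_array(),
                                   rtol=1e-12)
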