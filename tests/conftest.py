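import numpy as np
import pytest

import dwidecay as dw

WM_PARAMS = dw.ModTriExpParams(f0=0.15, f_slow=0.55,
                               adc_slow=600e-6, adc_fast=2000e-6)
BI_PARAMS = dw.BiExpParams(f_slow=0.6, adc_slow=600e-6, adc_fast=2000e-6)
TRI_PARAMS = dw.TriExpParams(f_very_slow=0.15, f_slow=0.55,
                             adc_very_slow=100e-6, adc_slow=600e-6,
                             adc_fast=2000e-6)

TRUE_PARAMS = {"biexp": BI_PARAMS, "triexp": TRI_PARAMS,
               "modtriexp": WM_PARAMS}


@pytest.fixture(scope="session")
def scheme():
    return dw.default_scheme()


@pytest.fixture(scope="session")
def wm_curve(scheme):
    """Noise-free white-matter-like modified tri-exponential curve."""
    return dw.predict_curve("modtriexp", WM_PARAMS, scheme)


@pytest.fixture(scope="session")
def noisy_curve_factory(scheme):
    """Factory for reproducible noisy curves from the WM truth.

    Additive Gaussian noise on the normalized scale (b=0 pinned to 1):
    a simple stand-in for averaged acquisition noise where the exact
    noise law does not matter.
    """
    clean = np.asarray(dw.predict_curve(
        "modtriexp", WM_PARAMS, scheme).s_over_s0)

    def make(seed, noise_sd=0.01):
        rng = np.random.default_rng(seed)
        y = clean + rng.normal(0.0, noise_sd, clean.size)
        y[0] = 1.0
        y = np.clip(y, 1e-6, None)
        return dw.DecayCurve(scheme, tuple(y))

    return make


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels(scheme, wm_curve):
    """Trigger numba compilation once so timings elsewhere stay honest."""
    dw.fit_voxel("modtriexp", wm_curve,
                 opts=dw.FitOptions(max_iterations=5))
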