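"""Constrained voxel-wise least-squares fitting of decay models.

The optimizer is a projected spectral (Barzilai-Borwein) gradient descent
with backtracking line search, followed by a projected Levenberg-Marquardt
refinement, run from the supplied initialization plus a small set of
deterministic alternative starts (the noisy objective can be multi-modal).
Correctness is anchored to the exhaustive :func:`grid_oracle` rather than
to optimizer internals.

Fitting uses only b-values up to ``FitOptions.fit_b_max``; by default the
highest b-value of the scheme (the ultra-high shell) is held out so it can
be predicted rather than fitted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .exceptions import InvalidParameterError, UnfittableVoxelError
from .signal_models import (
    BValueScheme,
    BiExpParams,
    DecayCurve,
    ModTriExpParams,
    ModelParams,
    N_FREE_PARAMS,
    TriExpParams,
    params_type_for,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitOptions",
    "FitResult",
    "InitRanges",
    "default_init",
    "normalize",
    "fit_voxel",
    "grid_oracle",
    "fit_volume",
    "stability_experiment",
    "DEFAULT_INIT_RANGES",
]

# Scaling between natural and kernel coordinates: kernel b = b/1e3,
# kernel ADC = ADC*1e3, so fractions and ADCs share an O(1) scale.
_B_SCALE = 1e-3
_ADC_SCALE = 1e3


@dataclass(frozen=True)
class FitOptions:
    """Options controlling a voxel fit.

    ``fit_b_max`` is the highest b-value (s/mm²) included in the fit; when
    None the largest b-value of the scheme is excluded (held out for
    prediction).  ``rel_tol`` is the relative RSS-decrease stopping
    threshold of the descent stage; ``step_init`` is the initial gradient
    step in scaled coordinates.  ``multistart`` enables the deterministic
    alternative starts.  ``seed`` governs any stochastic restart drawing
    (used by :func:`stability_experiment`).
    """

    max_iterations: int = 10_000
    rel_tol: float = 1e-9
    step_init: float = 1e-3
    fit_b_max: Optional[float] = None
    multistart: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be >= 1")
        if self.rel_tol <= 0:
            raise InvalidParameterError("rel_tol must be > 0")
        if self.step_init <= 0:
            raise InvalidParameterError("step_init must be > 0")

    def resolve_b_max(self, scheme: BValueScheme) -> float:
        if self.fit_b_max is None:
            return scheme.b_values[-2]
        scheme.index_of(self.fit_b_max)  # must be present
        return float(self.fit_b_max)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one voxel-level model fit.

    ``rss`` is the residual sum of squares on the normalized (S/S0) scale
    over the ``n_points`` fitted b-values; ``k`` is the number of free
    model parameters (S0 is not free, signals are pre-normalized).
    """

    model_id: str
    params: ModelParams
    rss: float
    n_points: int
    k: int
    converged: bool
    iterations: int
    fit_b_max: float
    degenerate: bool = False

    def __post_init__(self):
        if self.rss < 0:
            raise InvalidParameterError("rss must be >= 0")
        if self.k != N_FREE_PARAMS[self.model_id]:
            raise InvalidParameterError("k inconsistent with model")


@dataclass(frozen=True)
class InitRanges:
    """Per-parameter [low, high] bounds for random initial values."""

    ranges: Dict[str, Tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise InvalidParameterError(f"range for {name} has low > high")


#: Ranges of the random-initialization stability experiment (natural units).
DEFAULT_INIT_RANGES = InitRanges({
    "f0": (0.05, 0.10),
    "f_slow": (0.50, 0.60),
    "adc_slow": (500e-6, 800e-6),
    "adc_fast": (1900e-6, 2200e-6),
})

_DEFAULT_INITS = {
    "biexp": dict(f_slow=0.50, adc_slow=600e-6, adc_fast=2000e-6),
    "modtriexp": dict(f0=0.10, f_slow=0.50, adc_slow=600e-6, adc_fast=2000e-6),
    "triexp": dict(f_very_slow=0.10, f_slow=0.50, adc_very_slow=100e-6,
                   adc_slow=600e-6, adc_fast=2000e-6),
}


def default_init(model_id: str) -> ModelParams:
    """The standard initialization for a model.

    f_slow starts at 0.50 with ADC_slow 600e-6 and ADC_fast 2000e-6 mm²/s;
    the tri-exponential variants additionally start their very-slow /
    diffusion-limited fraction at 0.10 (ADC_very_slow at 100e-6 mm²/s).
    """
    try:
        kwargs = _DEFAULT_INITS[model_id]
    except KeyError:
        raise InvalidParameterError(f"unknown model id {model_id!r}") from None
    return params_type_for(model_id)(**kwargs)


def normalize(raw_signals: Sequence[float], scheme: BValueScheme,
              ) -> DecayCurve:
    """Normalize a raw signal vector to S/S0 (the b=0 measurement)."""
    raw = np.asarray(raw_signals, dtype=float)
    if raw.size != len(scheme):
        raise InvalidParameterError("signal length must match scheme")
    if not np.all(np.isfinite(raw)):
        raise UnfittableVoxelError("non-finite signal values")
    if raw[0] <= 0:
        raise UnfittableVoxelError("S0 must be > 0")
    s = raw / raw[0]
    if np.any(s <= 0):
        raise UnfittableVoxelError("nonpositive normalized signal")
    return DecayCurve(scheme=scheme, s_over_s0=tuple(s), s0=float(raw[0]))


def _to_kernel(x_nat: np.ndarray, nf: int) -> np.ndarray:
    x = np.array(x_nat, dtype=float)
    x[nf:] *= _ADC_SCALE
    return x


def _from_kernel(x_k: np.ndarray, nf: int) -> np.ndarray:
    x = np.array(x_k, dtype=float)
    x[nf:] /= _ADC_SCALE
    return x


def _extra_starts(x0_k: np.ndarray, nf: int) -> np.ndarray:
    """Deterministic alternative starts in kernel coordinates."""
    npar = x0_k.size
    starts = np.empty((5, npar))
    starts[0] = x0_k
    starts[0, 0] = 0.0                      # nested-model basin (fraction -> 0)
    starts[1] = x0_k
    starts[1, nf:] *= 0.5                   # slower decay regime
    starts[2] = x0_k
    starts[2, nf:] *= 2.0                   # faster decay regime
    starts[3, :nf] = 1.0 / (nf + 1.0)       # spread fractions evenly
    starts[3, nf:] = np.linspace(0.3, 3.0, npar - nf)
    starts[4] = x0_k
    starts[4, nf] = 0.0                     # zero-ADC basin (slowest ADC -> 0)
    return starts


def _label_swap(model_id: str, x_nat: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Reorder compartments so ADCs ascend, carrying fractions along."""
    x = np.array(x_nat, dtype=float)
    degenerate = False
    if model_id == "biexp":
        f_slow, a_s, a_f = x
        if a_s > a_f:
            x = np.array([1.0 - f_slow, a_f, a_s])
        degenerate = np.isclose(x[1], x[2])
    elif model_id == "modtriexp":
        f0, f_slow, a_s, a_f = x
        if a_s > a_f:
            x = np.array([f0, 1.0 - f0 - f_slow, a_f, a_s])
        degenerate = np.isclose(x[2], x[3])
    else:
        fvs, fs, a_vs, a_s, a_f = x
        ff = 1.0 - fvs - fs
        pairs = sorted(zip((a_vs, a_s, a_f), (fvs, fs, ff)))
        adcs = [p[0] for p in pairs]
        fracs = [p[1] for p in pairs]
        x = np.array([fracs[0], fracs[1], adcs[0], adcs[1], adcs[2]])
        degenerate = np.isclose(adcs[0], adcs[1]) or np.isclose(adcs[1], adcs[2])
    return x, bool(degenerate)


def _clean_fractions(x: np.ndarray, nf: int) -> np.ndarray:
    """Snap tiny numerical violations of the simplex constraints."""
    x = x.copy()
    x[:nf] = np.clip(x[:nf], 0.0, 1.0)
    s = x[:nf].sum()
    if s > 1.0:
        x[:nf] /= s
    return x


def _fit_arrays(model_id: str, b_fit: np.ndarray, y_fit: np.ndarray,
                init: ModelParams, opts: FitOptions,
                ) -> Tuple[np.ndarray, float, int, bool]:
    """Fit in kernel coordinates; returns (x_natural, rss, iters, converged)."""
    code = _kernels.MODEL_CODES[model_id]
    nf = _kernels.N_FRACTIONS[model_id]
    x0_k = _to_kernel(init.as_array(), nf)
    b_k = b_fit * _B_SCALE
    if opts.multistart:
        extra = _extra_starts(x0_k, nf)
    else:
        extra = np.empty((0, x0_k.size))
    x_k, rss, nit, conv = _kernels.fit_one(
        code, nf, x0_k, b_k, y_fit,
        opts.max_iterations, opts.rel_tol, opts.step_init, extra,
    )
    return _from_kernel(x_k, nf), float(rss), int(nit), bool(conv)


def fit_voxel(model_id: str, curve: DecayCurve,
              init: Optional[ModelParams] = None,
              opts: Optional[FitOptions] = None) -> FitResult:
    """Constrained least-squares fit of one model to one decay curve.

    Minimizes sum of squared residuals on the S/S0 scale over the b-values
    up to ``opts.fit_b_max`` subject to fractions >= 0, fraction sums <= 1
    and ADCs >= 0.  The returned parameters are label-swapped if needed so
    ADCs ascend.
    """
    opts = opts or FitOptions()
    init = init or default_init(model_id)
    if init.model_id != model_id:
        raise InvalidParameterError("init params do not match model")
    b_max = opts.resolve_b_max(curve.scheme)
    b = curve.scheme.b_array
    y = curve.signal_array
    if not np.all(np.isfinite(y)):
        raise UnfittableVoxelError("non-finite signal values")
    keep = b <= b_max
    b_fit, y_fit = b[keep], y[keep]
    x_nat, rss, nit, conv = _fit_arrays(model_id, b_fit, y_fit, init, opts)
    nf = _kernels.N_FRACTIONS[model_id]
    x_nat = _clean_fractions(x_nat, nf)
    x_nat, degenerate = _label_swap(model_id, x_nat)
    x_nat = _clean_fractions(x_nat, nf)  # swap can surface -0.0-scale fractions
    if degenerate:
        logger.debug("degenerate fit (equal ADCs) for %s", model_id)
    params = params_type_for(model_id).from_array(x_nat)
    return FitResult(
        model_id=model_id, params=params, rss=rss,
        n_points=int(keep.sum()), k=N_FREE_PARAMS[model_id],
        converged=conv, iterations=nit, fit_b_max=b_max,
        degenerate=degenerate,
    )


# Default lattice (natural units) used when a grid_spec omits a parameter.
_DEFAULT_GRID = {
    "f0": np.linspace(0.0, 0.4, 9),
    "f_very_slow": np.linspace(0.0, 0.4, 9),
    "f_slow": np.linspace(0.1, 0.9, 9),
    "adc_very_slow": np.linspace(0.0, 400e-6, 5),
    "adc_slow": np.linspace(200e-6, 1500e-6, 12),
    "adc_fast": np.linspace(1000e-6, 4000e-6, 12),
}

_PARAM_ORDER = {
    "biexp": ("f_slow", "adc_slow", "adc_fast"),
    "triexp": ("f_very_slow", "f_slow", "adc_very_slow", "adc_slow", "adc_fast"),
    "modtriexp": ("f0", "f_slow", "adc_slow", "adc_fast"),
}


def grid_oracle(model_id: str, curve: DecayCurve,
                grid_spec: Optional[Dict[str, Sequence[float]]] = None,
                opts: Optional[FitOptions] = None,
                polish: bool = True) -> FitResult:
    """Brute-force lattice search over the feasible parameter region.

    Evaluates the RSS at every feasible lattice point (infeasible fraction
    combinations are dropped) and returns the best, optionally refined by
    a local Levenberg-Marquardt descent from that point.  Intended as an
    independent check of :func:`fit_voxel`, not for production fitting.
    """
    opts = opts or FitOptions()
    names = _PARAM_ORDER[model_id]
    nf = _kernels.N_FRACTIONS[model_id]
    grid_spec = grid_spec or {}
    axes = [np.asarray(grid_spec.get(n, _DEFAULT_GRID[n]), dtype=float)
            for n in names]
    if any(a.size == 0 for a in axes):
        raise InvalidParameterError("empty lattice axis")
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    feasible = pts[:, :nf].sum(axis=1) <= 1.0 + 1e-12
    pts = pts[feasible]
    if pts.shape[0] == 0:
        raise InvalidParameterError("lattice has no feasible points")

    b_max = opts.resolve_b_max(curve.scheme)
    b = curve.scheme.b_array
    y = curve.signal_array
    keep = b <= b_max
    b_fit, y_fit = b[keep], y[keep]

    # vectorized forward model over the whole lattice
    decay = np.exp(-pts[:, nf:, None] * b_fit[None, None, :])
    fracs = pts[:, :nf]
    f_fast = 1.0 - fracs.sum(axis=1)
    if model_id == "modtriexp":
        signal = (fracs[:, [0]]
                  + fracs[:, [1]] * decay[:, 0, :]
                  + f_fast[:, None] * decay[:, 1, :])
    elif model_id == "biexp":
        signal = fracs[:, [0]] * decay[:, 0, :] + f_fast[:, None] * decay[:, 1, :]
    else:
        signal = (fracs[:, [0]] * decay[:, 0, :]
                  + fracs[:, [1]] * decay[:, 1, :]
                  + f_fast[:, None] * decay[:, 2, :])
    rss_all = np.square(signal - y_fit[None, :]).sum(axis=1)
    best = int(np.argmin(rss_all))
    x_nat = pts[best]
    rss = float(rss_all[best])
    nit = 0
    if polish:
        code = _kernels.MODEL_CODES[model_id]
        x_k, rss_p, nit = _kernels.lm_polish(
            code, nf, _to_kernel(x_nat, nf), b_fit * _B_SCALE, y_fit,
            500, 1e-15,
        )
        if rss_p < rss:
            rss = float(rss_p)
            x_nat = _from_kernel(x_k, nf)
    x_nat = _clean_fractions(x_nat, nf)
    x_nat, degenerate = _label_swap(model_id, x_nat)
    x_nat = _clean_fractions(x_nat, nf)
    params = params_type_for(model_id).from_array(x_nat)
    return FitResult(
        model_id=model_id, params=params, rss=rss,
        n_points=int(keep.sum()), k=N_FREE_PARAMS[model_id],
        converged=True, iterations=int(nit), fit_b_max=b_max,
        degenerate=degenerate,
    )


_MAP_FIELDS = {
    "biexp": (("f_slow", "f_slow_pct"), ("f_fast", "f_fast_pct"),
              ("adc_slow", "adc_slow_e6"), ("adc_fast", "adc_fast_e6")),
    "modtriexp": (("f0", "f0_pct"), ("f_slow", "f_slow_pct"),
                  ("f_fast", "f_fast_pct"),
                  ("adc_slow", "adc_slow_e6"), ("adc_fast", "adc_fast_e6")),
    "triexp": (("f_very_slow", "f_very_slow_pct"), ("f_slow", "f_slow_pct"),
               ("f_fast", "f_fast_pct"),
               ("adc_very_slow", "adc_very_slow_e6"),
               ("adc_slow", "adc_slow_e6"), ("adc_fast", "adc_fast_e6")),
}


def map_keys(model_id: str) -> Tuple[str, ...]:
    """Map names emitted by :func:`fit_volume` for a model (plus 'rss')."""
    return tuple(out for _, out in _MAP_FIELDS[model_id]) + ("rss",)


def fit_volume(model_id: str, data: np.ndarray, scheme: BValueScheme,
               mask: Optional[np.ndarray] = None,
               opts: Optional[FitOptions] = None,
               ) -> Dict[str, np.ndarray]:
    """Voxel-by-voxel fit over a 4-D magnitude series.

    Returns one 3-D map per parameter — fractions in percent, ADCs in
    1e-6 mm²/s (the conventional display units) — plus the RSS map.
    Unfittable voxels (S0 <= 0 or non-finite data) are NaN.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise InvalidParameterError("data must be 4-D (x, y, z, b)")
    if data.shape[3] != len(scheme):
        raise InvalidParameterError("4th dimension must match scheme length")
    shape = data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise InvalidParameterError("mask shape mismatch")
    opts = opts or FitOptions()
    init = default_init(model_id)
    maps = {out: np.full(shape, np.nan) for out in map_keys(model_id)}

    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        logger.warning("fit_volume: empty mask, returning empty maps")
        return maps
    n_unfittable = 0
    for (i, j, k) in idx:
        raw = data[i, j, k, :]
        try:
            curve = normalize(raw, scheme)
            res = fit_voxel(model_id, curve, init=init, opts=opts)
        except UnfittableVoxelError:
            n_unfittable += 1
            continue
        d = res.params.to_dict()
        for attr, out in _MAP_FIELDS[model_id]:
            if out.endswith("_pct"):
                maps[out][i, j, k] = getattr(res.params, attr) * 100.0
            else:
                maps[out][i, j, k] = d[attr + "_e6"]
        maps["rss"][i, j, k] = res.rss
    if n_unfittable:
        logger.info("fit_volume: %d unfittable voxel(s) set to NaN",
                    n_unfittable)
    return maps


def stability_experiment(model_id: str, curve: DecayCurve,
                         ranges: Optional[InitRanges] = None,
                         n_sets: int = 20,
                         seed: Optional[int] = None,
                         opts: Optional[FitOptions] = None):
    """Sensitivity of the fit to random initial values.

    Draws ``n_sets`` initializations uniformly from ``ranges`` (defaults
    to the declared experiment ranges for the modified tri-exponential
    model), fits each, and returns a pandas DataFrame of fitted parameter
    values (one row per initialization) whose ``.describe()`` gives the
    mean ± SD summary.
    """
    import pandas as pd

    if n_sets < 2:
        raise InvalidParameterError("n_sets must be >= 2 for an SD")
    ranges = ranges or DEFAULT_INIT_RANGES
    opts = opts or FitOptions()
    base = default_init(model_id)
    names = _PARAM_ORDER[model_id]
    for name in ranges.ranges:
        if name not in names:
            raise InvalidParameterError(
                f"range parameter {name!r} not in model {model_id!r}")
    rng = np.random.default_rng(seed if seed is not None else opts.seed)
    rows = []
    for _ in range(n_sets):
        kwargs = {}
        for name in names:
            lo, hi = ranges.ranges.get(
                name, (getattr(base, name), getattr(base, name)))
            kwargs[name] = rng.uniform(lo, hi)
        try:
            init = params_type_for(model_id)(**kwargs)
        except InvalidParameterError as err:
            raise InvalidParameterError(
                f"init ranges produce invalid parameters: {err}") from err
        res = fit_voxel(model_id, curve, init=init, opts=opts)
        row = {n: getattr(res.params, n) for n in names}
        row["f_fast"] = res.params.f_fast
        row["rss"] = res.rss
        rows.append(row)
    return pd.DataFrame(rows)
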