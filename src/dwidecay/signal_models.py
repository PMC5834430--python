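"""Closed-form multi-exponential diffusion decay models.

Three nested descriptions of the normalized diffusion-weighted signal
S(b)/S0 as a sum of freely-exchanging water compartments:

* bi-exponential            — slow + fast compartments,
* tri-exponential           — very-slow + slow + fast compartments,
* modified tri-exponential  — a strictly diffusion-limited compartment
  (apparent diffusion coefficient fixed at exactly zero, fraction ``f0``)
  plus slow and fast compartments.

ADC values are stored in mm²/s throughout the library; the conventional
display unit (1e-6 mm²/s) is used only at the I/O boundary.  Implied
fractions (``f_fast``) are always computed from the stored ones, never
stored, so compartment fractions sum to one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "BValueScheme",
    "DEFAULT_B_VALUES",
    "DEFAULT_NSA",
    "default_scheme",
    "BiExpParams",
    "TriExpParams",
    "ModTriExpParams",
    "DecayCurve",
    "mono_attenuation",
    "eval_biexp",
    "eval_triexp",
    "eval_modtriexp",
    "eval_model",
    "predict_curve",
    "MODEL_IDS",
    "N_FREE_PARAMS",
    "params_type_for",
]

#: The 17-b-value acquisition protocol (s/mm²).
DEFAULT_B_VALUES = (
    0, 10, 20, 30, 50, 70, 100, 150, 200, 300,
    500, 700, 1000, 2000, 3000, 5000, 8000,
)
#: Number of scan averages acquired at each b-value.
DEFAULT_NSA = (1, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 5, 5, 5, 5, 9, 12)

MODEL_IDS = ("biexp", "triexp", "modtriexp")

#: Free parameters per model (signals are pre-normalized, so S0 is not free).
N_FREE_PARAMS = {"biexp": 3, "triexp": 5, "modtriexp": 4}


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion weightings with their averaging counts.

    Parameters
    ----------
    b_values : sequence of float
        Diffusion weightings in s/mm², strictly increasing, starting at 0.
    nsa : sequence of int
        Number of scan averages per b-value (same length as ``b_values``).
    n_directions : int
        Number of orthogonal diffusion directions averaged by the scanner
        for b > 0 acquisitions.
    """

    b_values: tuple = DEFAULT_B_VALUES
    nsa: tuple = DEFAULT_NSA
    n_directions: int = 3

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        nsa = np.asarray(self.nsa, dtype=int)
        if b.size < 2:
            raise InvalidParameterError("scheme needs at least two b-values")
        if b[0] != 0:
            raise InvalidParameterError("first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise InvalidParameterError("b_values must be strictly increasing")
        if nsa.size != b.size:
            raise InvalidParameterError("nsa length must match b_values")
        if np.any(nsa < 1):
            raise InvalidParameterError("all NSA counts must be >= 1")
        if self.n_directions < 1:
            raise InvalidParameterError("n_directions must be >= 1")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        object.__setattr__(self, "nsa", tuple(int(x) for x in nsa))

    def __len__(self):
        return len(self.b_values)

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def nsa_array(self) -> np.ndarray:
        return np.asarray(self.nsa, dtype=int)

    def index_of(self, b: float) -> int:
        """Index of an exact b-value; raises if absent."""
        b_arr = self.b_array
        hits = np.nonzero(np.isclose(b_arr, float(b)))[0]
        if hits.size == 0:
            raise InvalidParameterError(f"b={b} not in scheme")
        return int(hits[0])

    def truncated(self, b_max: float) -> "BValueScheme":
        """Sub-scheme containing only b-values <= ``b_max``."""
        keep = self.b_array <= float(b_max)
        if keep.sum() < 2:
            raise InvalidParameterError("truncated scheme too short")
        return BValueScheme(
            tuple(np.asarray(self.b_values)[keep]),
            tuple(np.asarray(self.nsa)[keep]),
            self.n_directions,
        )


def default_scheme() -> BValueScheme:
    """The default 17-b-value, NSA-weighted, 3-direction acquisition scheme."""
    return BValueScheme()


def _check_fraction(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0.0 or value > 1.0:
        raise InvalidParameterError(f"{name}={value} outside [0, 1]")


def _check_adc(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0.0:
        raise InvalidParameterError(f"{name}={value} must be >= 0")


@dataclass(frozen=True)
class BiExpParams:
    """Bi-exponential compartment parameters.

    ``f_slow`` is the slow-compartment fraction; the fast fraction is implied
    (``f_fast = 1 - f_slow``).  ADCs are in mm²/s with ``adc_slow <= adc_fast``.
    """

    f_slow: float
    adc_slow: float
    adc_fast: float

    model_id = "biexp"
    k = 3

    def __post_init__(self):
        _check_fraction("f_slow", self.f_slow)
        _check_adc("adc_slow", self.adc_slow)
        _check_adc("adc_fast", self.adc_fast)
        if self.adc_fast < self.adc_slow:
            raise InvalidParameterError("adc_fast must be >= adc_slow")

    @property
    def f_fast(self) -> float:
        return 1.0 - self.f_slow

    def as_array(self) -> np.ndarray:
        """Kernel layout: fractions first, then ADCs (mm²/s)."""
        return np.array([self.f_slow, self.adc_slow, self.adc_fast])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "BiExpParams":
        return cls(float(x[0]), float(x[1]), float(x[2]))

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "f_slow": self.f_slow,
            "f_fast": self.f_fast,
            "adc_slow_e6": self.adc_slow * 1e6,
            "adc_fast_e6": self.adc_fast * 1e6,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiExpParams":
        return cls(
            f_slow=float(d["f_slow"]),
            adc_slow=float(d["adc_slow_e6"]) * 1e-6,
            adc_fast=float(d["adc_fast_e6"]) * 1e-6,
        )


@dataclass(frozen=True)
class TriExpParams:
    """Conventional tri-exponential compartment parameters.

    Three compartments (very-slow, slow, fast); the fast fraction is implied.
    ADCs ordered ``adc_very_slow <= adc_slow <= adc_fast``, all in mm²/s.
    """

    f_very_slow: float
    f_slow: float
    adc_very_slow: float
    adc_slow: float
    adc_fast: float

    model_id = "triexp"
    k = 5

    def __post_init__(self):
        _check_fraction("f_very_slow", self.f_very_slow)
        _check_fraction("f_slow", self.f_slow)
        if self.f_very_slow + self.f_slow > 1.0 + 1e-12:
            raise InvalidParameterError("f_very_slow + f_slow must be <= 1")
        _check_adc("adc_very_slow", self.adc_very_slow)
        _check_adc("adc_slow", self.adc_slow)
        _check_adc("adc_fast", self.adc_fast)
        if not (self.adc_very_slow <= self.adc_slow <= self.adc_fast):
            raise InvalidParameterError(
                "ADC ordering adc_very_slow <= adc_slow <= adc_fast violated"
            )

    @property
    def f_fast(self) -> float:
        return 1.0 - self.f_very_slow - self.f_slow

    def as_array(self) -> np.ndarray:
        return np.array([
            self.f_very_slow, self.f_slow,
            self.adc_very_slow, self.adc_slow, self.adc_fast,
        ])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "TriExpParams":
        return cls(float(x[0]), float(x[1]), float(x[2]), float(x[3]), float(x[4]))

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "f_very_slow": self.f_very_slow,
            "f_slow": self.f_slow,
            "f_fast": self.f_fast,
            "adc_very_slow_e6": self.adc_very_slow * 1e6,
            "adc_slow_e6": self.adc_slow * 1e6,
            "adc_fast_e6": self.adc_fast * 1e6,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TriExpParams":
        return cls(
            f_very_slow=float(d["f_very_slow"]),
            f_slow=float(d["f_slow"]),
            adc_very_slow=float(d["adc_very_slow_e6"]) * 1e-6,
            adc_slow=float(d["adc_slow_e6"]) * 1e-6,
            adc_fast=float(d["adc_fast_e6"]) * 1e-6,
        )


@dataclass(frozen=True)
class ModTriExpParams:
    """Modified tri-exponential parameters with a zero-ADC compartment.

    ``f0`` is the fraction of the strictly diffusion-limited compartment:
    water whose apparent diffusion coefficient is fixed at exactly zero, so
    its signal never decays with b.  The fast fraction is implied.
    """

    f0: float
    f_slow: float
    adc_slow: float
    adc_fast: float

    model_id = "modtriexp"
    k = 4

    def __post_init__(self):
        _check_fraction("f0", self.f0)
        _check_fraction("f_slow", self.f_slow)
        if self.f0 + self.f_slow > 1.0 + 1e-12:
            raise InvalidParameterError("f0 + f_slow must be <= 1")
        _check_adc("adc_slow", self.adc_slow)
        _check_adc("adc_fast", self.adc_fast)
        if self.adc_fast < self.adc_slow:
            raise InvalidParameterError("adc_fast must be >= adc_slow")

    @property
    def f_fast(self) -> float:
        return 1.0 - self.f0 - self.f_slow

    def as_array(self) -> np.ndarray:
        return np.array([self.f0, self.f_slow, self.adc_slow, self.adc_fast])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "ModTriExpParams":
        return cls(float(x[0]), float(x[1]), float(x[2]), float(x[3]))

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "f0": self.f0,
            "f_slow": self.f_slow,
            "f_fast": self.f_fast,
            "adc_slow_e6": self.adc_slow * 1e6,
            "adc_fast_e6": self.adc_fast * 1e6,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModTriExpParams":
        return cls(
            f0=float(d["f0"]),
            f_slow=float(d["f_slow"]),
            adc_slow=float(d["adc_slow_e6"]) * 1e-6,
            adc_fast=float(d["adc_fast_e6"]) * 1e-6,
        )


ModelParams = Union[BiExpParams, TriExpParams, ModTriExpParams]

_PARAM_TYPES = {
    "biexp": BiExpParams,
    "triexp": TriExpParams,
    "modtriexp": ModTriExpParams,
}


def params_type_for(model_id: str):
    """Parameter dataclass for a model id."""
    try:
        return _PARAM_TYPES[model_id]
    except KeyError:
        raise InvalidParameterError(f"unknown model id {model_id!r}") from None


def params_from_dict(d: dict) -> ModelParams:
    """Deserialize a parameter set from a flat key-value mapping."""
    return params_type_for(d["model"]).from_dict(d)


@dataclass(frozen=True)
class DecayCurve:
    """A per-voxel normalized decay curve over a b-value scheme."""

    scheme: BValueScheme
    s_over_s0: tuple
    s0: float = 1.0

    def __post_init__(self):
        s = np.asarray(self.s_over_s0, dtype=float)
        if s.size != len(self.scheme):
            raise InvalidParameterError("curve length must match scheme")
        if not np.all(np.isfinite(s)):
            raise InvalidParameterError("curve contains non-finite values")
        if not np.isclose(s[0], 1.0):
            raise InvalidParameterError("normalized curve must start at 1")
        if np.any(s <= 0):
            raise InvalidParameterError("normalized signals must be > 0")
        object.__setattr__(self, "s_over_s0", tuple(float(v) for v in s))

    @property
    def signal_array(self) -> np.ndarray:
        return np.asarray(self.s_over_s0, dtype=float)

    def value_at(self, b: float) -> float:
        return self.s_over_s0[self.scheme.index_of(b)]


def mono_attenuation(adc: float, b) -> float:
    """Single-compartment signal attenuation exp(-ADC * b).

    Parameters
    ----------
    adc : float
        Apparent diffusion coefficient in mm²/s, >= 0.
    b : float or array
        Diffusion weighting in s/mm², >= 0.
    """
    b = np.asarray(b, dtype=float)
    if adc < 0:
        raise InvalidParameterError("adc must be >= 0")
    if np.any(b < 0):
        raise InvalidParameterError("b must be >= 0")
    out = np.exp(-float(adc) * b)
    return float(out) if out.ndim == 0 else out


def eval_biexp(p: BiExpParams, b) -> float:
    """Bi-exponential normalized signal at weighting(s) ``b``."""
    return (
        p.f_slow * mono_attenuation(p.adc_slow, b)
        + p.f_fast * mono_attenuation(p.adc_fast, b)
    )


def eval_triexp(p: TriExpParams, b) -> float:
    """Conventional tri-exponential normalized signal at weighting(s) ``b``."""
    return (
        p.f_very_slow * mono_attenuation(p.adc_very_slow, b)
        + p.f_slow * mono_attenuation(p.adc_slow, b)
        + p.f_fast * mono_attenuation(p.adc_fast, b)
    )


def eval_modtriexp(p: ModTriExpParams, b) -> float:
    """Modified tri-exponential normalized signal at weighting(s) ``b``.

    The zero-ADC compartment contributes a constant floor ``f0``; as
    b grows the signal asymptotes to ``f0`` instead of zero.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise InvalidParameterError("b must be >= 0")
    out = (
        p.f0
        + p.f_slow * np.exp(-p.adc_slow * b)
        + p.f_fast * np.exp(-p.adc_fast * b)
    )
    return float(out) if out.ndim == 0 else out


_EVALUATORS = {
    "biexp": eval_biexp,
    "triexp": eval_triexp,
    "modtriexp": eval_modtriexp,
}


def eval_model(params: ModelParams, b):
    """Evaluate whichever decay model ``params`` belongs to."""
    return _EVALUATORS[params.model_id](params, b)


def predict_curve(model_id: str, params: ModelParams, scheme: BValueScheme,
                  s0: float = 1.0) -> DecayCurve:
    """Noise-free normalized decay curve of a model over a scheme."""
    if params.model_id != model_id:
        raise InvalidParameterError(
            f"params are for {params.model_id!r}, not {model_id!r}"
        )
    values = eval_model(params, scheme.b_array)
    return DecayCurve(scheme=scheme, s_over_s0=tuple(values), s0=s0)
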