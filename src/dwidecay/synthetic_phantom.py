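"""Synthetic multi-b-value magnitude phantoms with known ground truth.

Emulates a direction-averaged, NSA-weighted magnitude acquisition: each
measurement is the magnitude of the true signal plus complex Gaussian
noise (a Rician sample), and the scanner averages nsa x n_directions such
magnitudes per b-value (nsa only at b=0).  Magnitude averaging keeps the
Rician bias — the well-known positive noise floor at ultra-high b — which
is exactly the regime where a strictly diffusion-limited compartment must
be distinguished from noise.

The default two-class phantom has white-matter-like voxels (substantial
zero-ADC fraction, f0 = 0.15) and gray-matter-like voxels (f0 = 0.02),
with b=0 SNR per average of 28.2 and 31.2 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .exceptions import InvalidParameterError, UndefinedStatisticError
from .signal_models import (
    BValueScheme,
    ModTriExpParams,
    ModelParams,
    default_scheme,
    eval_model,
)

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "SNREstimate",
    "rician_sample",
    "acquire_voxel",
    "make_phantom",
    "snr_difference",
    "noise_to_s0_ratio",
    "default_wm_class",
    "default_gm_class",
    "two_class_phantom_spec",
]


@dataclass(frozen=True)
class TissueClass:
    """A tissue class: a decay model, its parameters, and the S0 scale."""

    name: str
    params: ModelParams
    s0_mean: float
    s0_sd: float = 0.0

    def __post_init__(self):
        if self.s0_mean <= 0:
            raise InvalidParameterError("s0_mean must be > 0")
        if self.s0_sd < 0:
            raise InvalidParameterError("s0_sd must be >= 0")

    @property
    def model_id(self) -> str:
        return self.params.model_id


def default_wm_class(s0_mean: float = 28.2) -> TissueClass:
    """White-matter-like tissue: f0 = 0.15, slow/fast ADCs 600/2000e-6 mm²/s.

    With unit noise SD, ``s0_mean`` 28.2 makes the b=0 per-average SNR 28.2.
    """
    return TissueClass(
        name="WM",
        params=ModTriExpParams(f0=0.15, f_slow=0.55,
                               adc_slow=600e-6, adc_fast=2000e-6),
        s0_mean=s0_mean,
    )


def default_gm_class(s0_mean: float = 31.2) -> TissueClass:
    """Gray-matter-like tissue: near-zero f0, faster diffusion."""
    return TissueClass(
        name="GM",
        params=ModTriExpParams(f0=0.02, f_slow=0.60,
                               adc_slow=800e-6, adc_fast=2200e-6),
        s0_mean=s0_mean,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue classes, acquisition scheme, and noise level.

    ``label_map`` holds integer class indices into ``classes``; negative
    labels mean background (zero signal, noise only).  ``sigma`` is the SD
    of each complex-channel Gaussian noise sample, in the same arbitrary
    units as the class S0 values.
    """

    shape: Tuple[int, int, int]
    label_map: np.ndarray = field(repr=False)
    classes: Tuple[TissueClass, ...]
    scheme: BValueScheme = field(default_factory=default_scheme)
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        labels = np.asarray(self.label_map)
        if labels.shape != tuple(self.shape):
            raise InvalidParameterError("label_map shape mismatch")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if labels.max(initial=-1) >= len(self.classes):
            raise InvalidParameterError("label references undefined class")
        object.__setattr__(self, "label_map", labels.astype(int))


@dataclass(frozen=True)
class SNREstimate:
    """Signal-to-noise ratio estimated by the two-acquisition difference
    method."""

    snr: float
    roi_mean_signal: float
    noise_sd: float

    def __post_init__(self):
        if self.snr < 0:
            raise InvalidParameterError("snr must be >= 0")


def rician_sample(true_signal, sigma: float, rng: np.random.Generator,
                  size=None):
    """Magnitude of (signal + complex Gaussian noise).

    Returns |(S + g1) + i g2| with g1, g2 ~ N(0, sigma²) independent.
    With sigma = 0 the true signal is returned exactly.
    """
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    true_signal = np.asarray(true_signal, dtype=float)
    if np.any(true_signal < 0):
        raise InvalidParameterError("true_signal must be >= 0")
    if sigma == 0:
        out = true_signal if size is None else np.broadcast_to(
            true_signal, size).copy()
        return float(out) if np.ndim(out) == 0 else out
    shape = size if size is not None else true_signal.shape
    re = true_signal + rng.normal(0.0, sigma, size=shape)
    im = rng.normal(0.0, sigma, size=shape)
    out = np.hypot(re, im)
    return float(out) if out.ndim == 0 else out


def acquire_voxel(tissue: TissueClass, scheme: BValueScheme, sigma: float,
                  rng: np.random.Generator,
                  s0: Optional[float] = None) -> np.ndarray:
    """Simulate one voxel's raw signal vector under the acquisition scheme.

    For each b-value the noise-free signal s0 * model(b) is sampled
    nsa x n_directions times (nsa only at b=0, where diffusion weighting
    needs no directions) as independent Rician magnitudes, and the samples
    are averaged — so the effective noise SD shrinks as 1/sqrt(averages)
    while the Rician bias of each magnitude sample survives the averaging.
    """
    if s0 is None:
        s0 = tissue.s0_mean
    b = scheme.b_array
    clean = s0 * np.asarray(eval_model(tissue.params, b), dtype=float)
    nsa = scheme.nsa_array
    out = np.empty(len(scheme))
    for i in range(len(scheme)):
        n_avg = int(nsa[i]) * (scheme.n_directions if b[i] > 0 else 1)
        samples = rician_sample(clean[i], sigma, rng, size=(n_avg,))
        out[i] = float(np.mean(samples))
    return out


def make_phantom(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Generate the 4-D magnitude dataset plus ground-truth maps.

    Deterministic given ``spec.seed``: every voxel gets its own random
    stream spawned from (seed, flat voxel index), so results never depend
    on traversal order.  Returns a dict with 'data' (4-D), 'labels' (3-D
    int), and one 'truth_<param>' 3-D map per ground-truth parameter
    (fractions as fractions, ADCs in mm²/s; NaN where a class lacks the
    parameter or in background).
    """
    shape = tuple(spec.shape)
    nb = len(spec.scheme)
    data = np.zeros(shape + (nb,))
    labels = spec.label_map

    truth_keys = set()
    for cls in spec.classes:
        d = cls.params.to_dict()
        truth_keys.update(k for k in d if k != "model")
    truth = {k: np.full(shape, np.nan) for k in truth_keys}
    truth["s0"] = np.full(shape, np.nan)

    for flat, (i, j, k) in enumerate(np.ndindex(shape)):
        lbl = labels[i, j, k]
        rng = np.random.default_rng([spec.seed, flat])
        if lbl < 0:
            data[i, j, k, :] = rician_sample(
                np.zeros(nb), spec.sigma, rng) if spec.sigma > 0 else 0.0
            continue
        cls = spec.classes[lbl]
        s0 = cls.s0_mean if cls.s0_sd == 0 else max(
            rng.normal(cls.s0_mean, cls.s0_sd), 1e-3)
        data[i, j, k, :] = acquire_voxel(cls, spec.scheme, spec.sigma, rng,
                                         s0=s0)
        d = cls.params.to_dict()
        for key, val in d.items():
            if key != "model":
                truth[key][i, j, k] = val
        truth["s0"][i, j, k] = s0

    out = {"data": data, "labels": labels.copy()}
    out.update({f"truth_{k}": v for k, v in truth.items()})
    return out


def snr_difference(image_a: np.ndarray, image_b: np.ndarray,
                   roi: np.ndarray) -> SNREstimate:
    """SNR from two repeated acquisitions via the difference method.

    SNR = mean over the ROI of (a+b)/2, divided by the SD over the ROI of
    (a-b)/sqrt(2).  Identical images make the noise SD zero and the SNR
    undefined.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    roi = np.asarray(roi).astype(bool)
    if a.shape != b.shape or roi.shape != a.shape:
        raise InvalidParameterError("images and ROI must share a shape")
    if not roi.any():
        raise InvalidParameterError("ROI is empty")
    mean_signal = float(np.mean((a[roi] + b[roi]) / 2.0))
    noise_sd = float(np.std((a[roi] - b[roi]) / np.sqrt(2.0), ddof=1))
    if noise_sd == 0:
        raise UndefinedStatisticError(
            "zero difference SD: SNR undefined for identical images")
    return SNREstimate(snr=mean_signal / noise_sd,
                       roi_mean_signal=mean_signal, noise_sd=noise_sd)


def noise_to_s0_ratio(remaining_ratio: float, snr_at_b: float) -> float:
    """Ratio of the noise level at a high-b image to the signal at b=0.

    With S(b)/S0 = ``remaining_ratio`` and the measured SNR at that
    b-value, noise/S0 = remaining_ratio / snr_at_b.  Used to argue that a
    measured signal floor is not a noise floor.
    """
    if snr_at_b <= 0:
        raise InvalidParameterError("snr_at_b must be > 0")
    return float(remaining_ratio) / float(snr_at_b)


def two_class_phantom_spec(shape: Tuple[int, int, int] = (32, 32, 4),
                           sigma: float = 1.0,
                           seed: int = 0,
                           scheme: Optional[BValueScheme] = None,
                           ) -> PhantomSpec:
    """The default WM/GM block phantom.

    The volume is split into two equal blocks along the first axis:
    white-matter-like voxels (label 0) in the first half, gray-matter-like
    (label 1) in the second.
    """
    labels = np.zeros(shape, dtype=int)
    labels[shape[0] // 2:, :, :] = 1
    return PhantomSpec(
        shape=shape,
        label_map=labels,
        classes=(default_wm_class(), default_gm_class()),
        scheme=scheme or default_scheme(),
        sigma=sigma,
        seed=seed,
    )
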