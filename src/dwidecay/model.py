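"""Model/Results interface for single-curve decay fitting.

The three decay models are exposed as model classes built from a decay
curve whose ``fit()`` returns a results object carrying the estimates and
ranking statistics:

>>> from dwidecay import ModifiedTriExponentialModel, default_scheme
>>> model = ModifiedTriExponentialModel.from_signals(raw, default_scheme())
>>> res = model.fit()
>>> res.params.f0, res.rss, res.aicc
>>> print(res.summary())

``compare()`` on any model class ranks all three models on one curve.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import model_selection as ms
from .exceptions import InvalidParameterError
from .fitting import FitOptions, FitResult, default_init, fit_voxel, normalize
from .signal_models import (
    BValueScheme,
    DecayCurve,
    ModelParams,
    eval_model,
)

__all__ = [
    "DecayModel",
    "BiExponentialModel",
    "TriExponentialModel",
    "ModifiedTriExponentialModel",
    "DecayFitResults",
    "model_class_for",
]


class DecayModel:
    """Base class: a decay model bound to one normalized decay curve."""

    model_id: str = None

    def __init__(self, curve: DecayCurve):
        if self.model_id is None:
            raise TypeError("use a concrete model subclass")
        self.curve = curve

    @classmethod
    def from_signals(cls, raw_signals: Sequence[float],
                     scheme: BValueScheme) -> "DecayModel":
        """Build from raw (un-normalized) signals; S0 is the b=0 entry."""
        return cls(normalize(raw_signals, scheme))

    @classmethod
    def from_dataframe(cls, df, b_col: str = "b", signal_col: str = "signal",
                       nsa_col: Optional[str] = None,
                       n_directions: int = 3) -> "DecayModel":
        """Build from a tidy DataFrame with one row per b-value."""
        df = df.sort_values(b_col)
        b = tuple(float(v) for v in df[b_col])
        nsa = (tuple(int(v) for v in df[nsa_col]) if nsa_col
               else tuple([1] * len(b)))
        scheme = BValueScheme(b, nsa, n_directions)
        return cls.from_signals(np.asarray(df[signal_col], dtype=float),
                                scheme)

    def fit(self, init: Optional[ModelParams] = None,
            options: Optional[FitOptions] = None) -> "DecayFitResults":
        """Constrained least-squares fit; returns a results object."""
        res = fit_voxel(self.model_id, self.curve, init=init, opts=options)
        return DecayFitResults(self, res, options or FitOptions())

    def default_init(self) -> ModelParams:
        return default_init(self.model_id)

    def predict(self, params: ModelParams, b=None):
        """Forward-evaluate given parameters (defaults to the scheme's b)."""
        if b is None:
            b = self.curve.scheme.b_array
        return eval_model(params, b)

    @staticmethod
    def compare(curve: DecayCurve, options: Optional[FitOptions] = None,
                include_press: bool = True) -> ms.SelectionScores:
        """Rank all three models on one curve (RSS, AICc, PRESS, SPE)."""
        return ms.compare_models(curve, opts=options,
                                 include_press=include_press)


class BiExponentialModel(DecayModel):
    """Slow + fast freely-diffusing compartments."""

    model_id = "biexp"


class TriExponentialModel(DecayModel):
    """Very-slow + slow + fast freely-diffusing compartments."""

    model_id = "triexp"


class ModifiedTriExponentialModel(DecayModel):
    """Strictly diffusion-limited (zero-ADC) + slow + fast compartments."""

    model_id = "modtriexp"


_MODEL_CLASSES = {
    "biexp": BiExponentialModel,
    "triexp": TriExponentialModel,
    "modtriexp": ModifiedTriExponentialModel,
}


def model_class_for(model_id: str):
    try:
        return _MODEL_CLASSES[model_id]
    except KeyError:
        raise InvalidParameterError(f"unknown model id {model_id!r}") from None


class DecayFitResults:
    """Estimates and diagnostics from fitting one decay model to one curve."""

    def __init__(self, model: DecayModel, result: FitResult,
                 options: FitOptions):
        self.model = model
        self.result = result
        self.options = options

    # -- pass-through estimate fields ------------------------------------
    @property
    def params(self) -> ModelParams:
        return self.result.params

    @property
    def rss(self) -> float:
        return self.result.rss

    @property
    def k(self) -> int:
        return self.result.k

    @property
    def n_points(self) -> int:
        return self.result.n_points

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def iterations(self) -> int:
        return self.result.iterations

    # -- ranking statistics ----------------------------------------------
    @property
    def aicc(self) -> float:
        """Small-sample corrected AIC of this fit."""
        return ms.aicc(self.k, self.n_points, max(self.rss, ms.RSS_FLOOR))

    def predict(self, b=None):
        """Model signal at the fitted parameters."""
        return self.model.predict(self.params, b)

    def predict_heldout(self, b_heldout: Optional[float] = None) -> float:
        """Prediction at a b-value excluded from the fit (default: the
        scheme's highest)."""
        if b_heldout is None:
            b_heldout = self.model.curve.scheme.b_values[-1]
        return ms.predict_heldout(self.result, self.model.curve.scheme,
                                  b_heldout)

    def spe(self, b_heldout: Optional[float] = None) -> float:
        """Squared prediction error at the held-out b-value."""
        if b_heldout is None:
            b_heldout = self.model.curve.scheme.b_values[-1]
        measured = self.model.curve.value_at(b_heldout)
        return ms.spe(measured, self.predict_heldout(b_heldout))

    def press(self) -> float:
        """Leave-one-out predicted residual sum of squares."""
        return ms.press(self.result.model_id, self.model.curve,
                        opts=self.options)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table (fractions in %, ADCs in 1e-6 mm²/s)."""
        d = self.params.to_dict()
        lines = [
            f"{type(self.model).__name__} fit",
            "=" * 44,
            f"{'n fitted b-values':<28}{self.n_points:>16}",
            f"{'free parameters (k)':<28}{self.k:>16}",
            f"{'RSS':<28}{self.rss:>16.6e}",
            f"{'AICc':<28}{self.aicc:>16.2f}",
            f"{'converged':<28}{str(self.converged):>16}",
            f"{'iterations':<28}{self.iterations:>16}",
            "-" * 44,
        ]
        for key, val in d.items():
            if key == "model":
                continue
            if key.endswith("_e6"):
                label = key[:-3] + " [1e-6 mm2/s]"
                lines.append(f"{label:<28}{val:>16.1f}")
            else:
                lines.append(f"{key + ' [%]':<28}{val * 100:>16.2f}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def plot(self, ax=None, heldout: bool = True):
        """Semilog plot of the measured curve and the fitted model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scheme = self.model.curve.scheme
        b = scheme.b_array
        y = self.model.curve.signal_array
        fitted = b <= self.result.fit_b_max
        ax.semilogy(b[fitted], y[fitted], "o", label="measured (fitted)")
        if heldout and (~fitted).any():
            ax.semilogy(b[~fitted], y[~fitted], "s", label="measured (held out)")
        bb = np.linspace(0, b[-1], 300)
        ax.semilogy(bb, self.predict(bb), "-",
                    label=f"{self.result.model_id} fit")
        ax.set_xlabel("b [s/mm$^2$]")
        ax.set_ylabel("S/S$_0$")
        ax.legend()
        return ax

    def __repr__(self):
        return (f"<DecayFitResults {self.result.model_id} "
                f"rss={self.rss:.3e} aicc={self.aicc:.2f}>")
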