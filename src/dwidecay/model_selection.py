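"""Model-ranking statistics: RSS, AICc, leave-one-out PRESS, and the
squared prediction error (SPE) at a held-out ultra-high b-value.

AICc is the small-sample corrected Akaike information criterion

    AICc = 2k + N ln(RSS/N) + 2k(k+1) / (N - k - 1)

with k free parameters and N fitted points; lower is better.  PRESS
refits the model N times, each time leaving one fitted b-value out and
predicting it, and sums the squared prediction errors.  SPE compares the
measured and model-predicted normalized signal at a b-value that was
never fitted (by default the highest shell of the scheme).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .exceptions import InvalidParameterError, UnfittableVoxelError
from .fitting import FitOptions, FitResult, default_init, fit_voxel
from .signal_models import (
    BValueScheme,
    DecayCurve,
    MODEL_IDS,
    N_FREE_PARAMS,
    eval_model,
)

logger = logging.getLogger(__name__)

__all__ = [
    "aicc",
    "spe",
    "predict_heldout",
    "press",
    "compare_models",
    "SelectionScores",
    "RSS_FLOOR",
]

#: RSS values below this are floored before the AICc logarithm (noise-free
#: fits can reach RSS = 0, where the criterion is undefined).
RSS_FLOOR = 1e-30


def aicc(k: int, n: int, rss: float) -> float:
    """Small-sample corrected Akaike information criterion.

    Raises if ``rss`` is zero/negative (log undefined — callers floor at
    :data:`RSS_FLOOR` first) or if ``n <= k + 1`` (correction undefined).
    """
    if n <= k + 1:
        raise InvalidParameterError("AICc requires n > k + 1")
    if rss <= 0:
        raise InvalidParameterError("AICc requires rss > 0")
    return 2.0 * k + n * np.log(rss / n) + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _floored_aicc(k: int, n: int, rss: float) -> float:
    if rss < RSS_FLOOR:
        warnings.warn("RSS below floor; flooring before AICc logarithm",
                      RuntimeWarning, stacklevel=2)
        rss = RSS_FLOOR
    return aicc(k, n, rss)


def spe(s_measured: float, s_predicted: float) -> float:
    """Squared prediction error (Sm - Sp)² between measured and predicted
    normalized signal."""
    if not (np.isfinite(s_measured) and np.isfinite(s_predicted)):
        raise InvalidParameterError("SPE inputs must be finite")
    d = float(s_measured) - float(s_predicted)
    return d * d


def predict_heldout(fit: FitResult, scheme: BValueScheme,
                    b_heldout: float) -> float:
    """Forward-evaluate a fitted model at a b-value excluded from the fit.

    Raises if ``b_heldout`` was among the fitted b-values (that would leak
    the measurement into its own prediction).
    """
    if float(b_heldout) <= fit.fit_b_max:
        raise InvalidParameterError(
            f"b={b_heldout} was used in fitting (fit_b_max={fit.fit_b_max})")
    return float(eval_model(fit.params, float(b_heldout)))


def press(model_id: str, curve: DecayCurve,
          opts: Optional[FitOptions] = None) -> float:
    """Leave-one-out predicted residual sum of squares.

    Each fitted b-value is removed in turn; the model is refitted from the
    default initialization on the remaining points and the removed point
    predicted.  The b=0 fold contributes exactly zero (every model equals
    1 there) but stays in the cycle so the fold count matches the AICc N.
    """
    opts = opts or FitOptions()
    b_max = opts.resolve_b_max(curve.scheme)
    scheme = curve.scheme
    b = scheme.b_array
    y = curve.signal_array
    fit_idx = np.nonzero(b <= b_max)[0]
    if fit_idx.size < N_FREE_PARAMS[model_id] + 2:
        raise InvalidParameterError("too few b-values for leave-one-out")
    init = default_init(model_id)
    total = 0.0
    for leave in fit_idx:
        if b[leave] == 0.0:
            continue  # prediction at b=0 is exactly 1: zero contribution
        keep = fit_idx[fit_idx != leave]
        sub_scheme = BValueScheme(
            tuple(b[keep]), tuple(scheme.nsa_array[keep]), scheme.n_directions)
        sub_curve = DecayCurve(sub_scheme, tuple(y[keep]), s0=curve.s0)
        sub_opts = FitOptions(
            max_iterations=opts.max_iterations, rel_tol=opts.rel_tol,
            step_init=opts.step_init, fit_b_max=float(b[keep][-1]),
            multistart=opts.multistart, seed=opts.seed)
        res = fit_voxel(model_id, sub_curve, init=init, opts=sub_opts)
        pred = float(eval_model(res.params, float(b[leave])))
        total += (y[leave] - pred) ** 2
    return total


@dataclass(frozen=True)
class SelectionScores:
    """Per-voxel model-ranking statistics for a set of candidate models."""

    rss: Dict[str, float]
    aicc: Dict[str, float]
    press: Dict[str, Optional[float]]
    spe: Dict[str, float]
    s_measured_heldout: float
    s_predicted_heldout: Dict[str, float]
    b_heldout: float
    fits: Dict[str, FitResult] = field(repr=False, default=None)

    def best(self, statistic: str) -> str:
        """Model id with the lowest value of a statistic."""
        scores = getattr(self, statistic)
        valid = {m: v for m, v in scores.items() if v is not None}
        return min(valid, key=valid.get)

    def worst(self, statistic: str) -> str:
        scores = getattr(self, statistic)
        valid = {m: v for m, v in scores.items() if v is not None}
        return max(valid, key=valid.get)


def compare_models(curve: DecayCurve,
                   opts: Optional[FitOptions] = None,
                   models: Sequence[str] = MODEL_IDS,
                   include_press: bool = True) -> SelectionScores:
    """Fit each candidate model and compute its ranking statistics.

    The models are fitted on the b-values up to ``opts.fit_b_max`` (by
    default all but the highest shell); AICc uses that fitted-point count
    and the model-specific k.  SPE compares each model's prediction at the
    held-out highest b-value with the measurement there.
    """
    opts = opts or FitOptions()
    b_max = opts.resolve_b_max(curve.scheme)
    b_heldout = curve.scheme.b_values[-1]
    if b_heldout <= b_max:
        raise InvalidParameterError(
            "curve must include a b-value beyond fit_b_max for SPE")
    s_measured = curve.value_at(b_heldout)

    rss, aic, prs, spes, preds, fits = {}, {}, {}, {}, {}, {}
    for model_id in models:
        res = fit_voxel(model_id, curve, opts=opts)
        fits[model_id] = res
        rss[model_id] = res.rss
        aic[model_id] = _floored_aicc(res.k, res.n_points, res.rss)
        pred = predict_heldout(res, curve.scheme, b_heldout)
        preds[model_id] = pred
        spes[model_id] = spe(s_measured, pred)
        if include_press:
            try:
                prs[model_id] = press(model_id, curve, opts=opts)
            except (InvalidParameterError, UnfittableVoxelError) as err:
                logger.warning("PRESS failed for %s: %s", model_id, err)
                prs[model_id] = None
        else:
            prs[model_id] = None
    return SelectionScores(
        rss=rss, aicc=aic, press=prs, spe=spes,
        s_measured_heldout=s_measured, s_predicted_heldout=preds,
        b_heldout=b_heldout, fits=fits,
    )
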