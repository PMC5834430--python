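"""End-to-end orchestration: fits, per-voxel model ranking, ROI summaries,
paired Wilcoxon comparisons, and report tables.

ROI aggregation follows the reporting convention of the study design this
package implements: compartment parameters are summarized as mean ± SD,
ranking statistics (RSS, AICc, PRESS, SPE) as median (q1, q3) with linear
interpolation between order statistics.  Wilcoxon signed-rank pairing is
voxel-wise within an ROI by default (subject-level pairing is also
available through the ``pairs`` argument of the statistical helper); no
multiple-testing correction is applied, but the report notes how many
comparisons were run.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .exceptions import InvalidParameterError, UndefinedStatisticError
from .fitting import FitOptions, fit_volume, map_keys, normalize
from .io import save_volume, save_yaml, write_btable
from .model_selection import compare_models
from .signal_models import MODEL_IDS, BValueScheme
from .synthetic_phantom import PhantomSpec, make_phantom, two_class_phantom_spec

logger = logging.getLogger(__name__)

__all__ = [
    "ROISummary",
    "ComparisonResult",
    "roi_summary",
    "wilcoxon_signed_rank",
    "score_volume",
    "run_full_analysis",
]

STATISTICS = ("rss", "aicc", "press", "spe")


@dataclass(frozen=True)
class ROISummary:
    """Per-ROI aggregation: parameters as mean ± SD, scores as quartiles."""

    roi: str
    voxel_count: int
    params: Dict[str, Tuple[float, float]]          # key -> (mean, sd)
    scores: Dict[str, Tuple[float, float, float]]   # key -> (median, q1, q3)

    def __post_init__(self):
        if self.voxel_count < 1:
            raise InvalidParameterError("ROI must contain >= 1 voxel")
        for key, (med, q1, q3) in self.scores.items():
            if not (q1 <= med <= q3):
                raise InvalidParameterError(f"quartiles out of order for {key}")


@dataclass(frozen=True)
class ComparisonResult:
    """A paired Wilcoxon comparison of one statistic between two models."""

    roi: str
    statistic: str
    model_a: str
    model_b: str
    p_value: float
    median_difference: float
    n_pairs: int

    @property
    def direction(self) -> str:
        if np.isnan(self.p_value):
            return "undefined"
        if self.median_difference < 0:
            return f"{self.model_a} < {self.model_b}"
        if self.median_difference > 0:
            return f"{self.model_a} > {self.model_b}"
        return "equal medians"


def roi_summary(maps: Dict[str, np.ndarray], roi_mask: np.ndarray,
                roi_name: str = "ROI",
                param_keys: Optional[Sequence[str]] = None,
                score_keys: Optional[Sequence[str]] = None) -> ROISummary:
    """Summarize maps within one ROI, ignoring unfittable (NaN) voxels.

    Keys not listed in ``param_keys``/``score_keys`` are classified by
    naming convention: statistics ('rss', 'aicc', 'press', 'spe' prefixes)
    get median (q1, q3); everything else gets mean ± SD.
    """
    roi_mask = np.asarray(roi_mask).astype(bool)
    if not roi_mask.any():
        raise InvalidParameterError("empty ROI")
    if param_keys is None or score_keys is None:
        auto_scores = tuple(k for k in maps
                            if k.split("_")[0] in STATISTICS)
        score_keys = score_keys if score_keys is not None else auto_scores
        param_keys = (param_keys if param_keys is not None
                      else tuple(k for k in maps if k not in score_keys))
    params, scores = {}, {}
    count = 0
    for key in param_keys:
        vals = maps[key][roi_mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise InvalidParameterError(f"ROI has no valid voxels for {key}")
        params[key] = (float(np.mean(vals)), float(np.std(vals, ddof=1))
                       if vals.size > 1 else 0.0)
        count = max(count, vals.size)
    for key in score_keys:
        vals = maps[key][roi_mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise InvalidParameterError(f"ROI has no valid voxels for {key}")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        scores[key] = (float(med), float(q1), float(q3))
        count = max(count, vals.size)
    return ROISummary(roi=roi_name, voxel_count=int(count),
                      params=params, scores=scores)


def wilcoxon_signed_rank(paired_a: Sequence[float],
                         paired_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded (Wilcoxon's convention); the exact null
    distribution is enumerated for small samples without ties and a
    tie-corrected normal approximation is used otherwise.  Returns NaN when
    every difference is zero (the test is undefined).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("paired samples must share a length")
    if a.size < 6:
        raise InvalidParameterError("need at least 6 pairs")
    d = a - b
    if np.all(d == 0):
        return float("nan")
    res = stats.wilcoxon(a, b, zero_method="wilcox",
                         alternative="two-sided", method="auto")
    return float(res.pvalue)


def score_volume(data: np.ndarray, scheme: BValueScheme,
                 mask: Optional[np.ndarray] = None,
                 opts: Optional[FitOptions] = None,
                 models: Sequence[str] = MODEL_IDS,
                 include_press: bool = True) -> Dict[str, np.ndarray]:
    """Per-voxel model-ranking maps (rss/aicc/press/spe per model).

    Returns a dict of 3-D maps named ``<statistic>_<model>``; unfittable
    voxels are NaN.
    """
    data = np.asarray(data, dtype=float)
    shape = data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    opts = opts or FitOptions()
    maps = {f"{stat}_{m}": np.full(shape, np.nan)
            for stat in STATISTICS for m in models}
    n_unfittable = 0
    for (i, j, k) in np.argwhere(mask):
        try:
            curve = normalize(data[i, j, k, :], scheme)
            scores = compare_models(curve, opts=opts, models=models,
                                    include_press=include_press)
        except Exception:
            n_unfittable += 1
            continue
        for m in models:
            maps[f"rss_{m}"][i, j, k] = scores.rss[m]
            maps[f"aicc_{m}"][i, j, k] = scores.aicc[m]
            if scores.press[m] is not None:
                maps[f"press_{m}"][i, j, k] = scores.press[m]
            maps[f"spe_{m}"][i, j, k] = scores.spe[m]
    if n_unfittable:
        logger.info("score_volume: %d unfittable voxel(s)", n_unfittable)
    return maps


def _format_cell(med: float, q1: float, q3: float) -> str:
    return f"{med:.6g} ({q1:.6g}, {q3:.6g})"


def run_full_analysis(config: dict) -> dict:
    """Run the full phantom-or-data analysis and write the report bundle.

    Config keys (all optional except ``output_dir``):

    * ``output_dir`` — where maps, tables and the log are written.
    * ``phantom`` — dict for :func:`two_class_phantom_spec` (``shape``,
      ``sigma``, ``seed``); used when no ``data`` volume is given.
    * ``data`` / ``btable`` — paths to a 4-D NIfTI and its b-table, for
      real acquisitions.
    * ``rois`` — mapping of ROI name to NIfTI mask path; for phantoms the
      class regions are used automatically.
    * ``models`` — model ids to compare (default: all three).
    * ``include_press`` — whether to compute leave-one-out PRESS maps.
    * ``fit`` — FitOptions fields.

    Returns a dict with the parameter maps, score maps, ROI summaries,
    comparison results and output paths.  Deterministic given the seed.
    """
    out_dir = config["output_dir"]
    os.makedirs(out_dir, exist_ok=True)
    models = tuple(config.get("models", MODEL_IDS))
    include_press = bool(config.get("include_press", True))
    opts = FitOptions(**config.get("fit", {}))

    rois: Dict[str, np.ndarray] = {}
    if "data" in config:
        from .io import load_volume, read_btable

        data, _ = load_volume(config["data"])
        scheme = read_btable(config["btable"])
        seed = int(config.get("seed", 0))
        for name, path in config.get("rois", {}).items():
            mask, _ = load_volume(path)
            if mask.shape != data.shape[:3]:
                raise InvalidParameterError(
                    f"ROI {name!r} not co-registered with the data volume")
            rois[name] = mask > 0
    else:
        pcfg = dict(config.get("phantom", {}))
        seed = int(pcfg.pop("seed", config.get("seed", 0)))
        spec = two_class_phantom_spec(
            shape=tuple(pcfg.get("shape", (12, 12, 2))),
            sigma=float(pcfg.get("sigma", 1.0)), seed=seed)
        phantom = make_phantom(spec)
        data = phantom["data"]
        scheme = spec.scheme
        for idx, cls in enumerate(spec.classes):
            rois[cls.name] = phantom["labels"] == idx
        save_volume(os.path.join(out_dir, "phantom.nii.gz"), data)
        save_volume(os.path.join(out_dir, "labels.nii.gz"),
                    phantom["labels"].astype(float))
        write_btable(os.path.join(out_dir, "btable.txt"), scheme)
        save_yaml(os.path.join(out_dir, "ground_truth.yaml"), {
            cls.name: cls.params.to_dict() for cls in spec.classes})
    if not rois:
        raise InvalidParameterError("no ROIs defined")
    full_mask = np.zeros(data.shape[:3], dtype=bool)
    for m in rois.values():
        full_mask |= m

    # parameter maps per model, and per-voxel ranking maps
    param_maps = {m: fit_volume(m, data, scheme, mask=full_mask, opts=opts)
                  for m in models}
    score_maps = score_volume(data, scheme, mask=full_mask, opts=opts,
                              models=models, include_press=include_press)
    for m in models:
        for key, arr in param_maps[m].items():
            save_volume(os.path.join(out_dir, f"map_{m}_{key}.nii.gz"), arr)
    for key, arr in score_maps.items():
        save_volume(os.path.join(out_dir, f"score_{key}.nii.gz"), arr)

    # ROI summaries -> paper-style tables
    summaries = {}
    stat_rows = {stat: [] for stat in STATISTICS}
    param_rows = []
    long_rows = []
    for roi_name, mask in rois.items():
        merged = dict(score_maps)
        for m in models:
            merged.update({f"{key}_{m}": arr
                           for key, arr in param_maps[m].items()})
        # drop statistics that were not computed (e.g. PRESS disabled)
        merged = {key: arr for key, arr in merged.items()
                  if np.isfinite(arr[mask]).any()}
        summary = roi_summary(merged, mask, roi_name=roi_name)
        summaries[roi_name] = summary
        for stat in STATISTICS:
            row = {"roi": roi_name}
            for m in models:
                key = f"{stat}_{m}"
                if key in summary.scores:
                    row[m] = _format_cell(*summary.scores[key])
            stat_rows[stat].append(row)
        for key, (mean, sd) in sorted(summary.params.items()):
            param_rows.append({"roi": roi_name, "map": key,
                               "mean": round(mean, 6), "sd": round(sd, 6)})
        for key, (med, q1, q3) in sorted(summary.scores.items()):
            stat, m = key.split("_", 1)
            long_rows.append({"roi": roi_name, "model": m, "statistic": stat,
                              "median": med, "q1": q1, "q3": q3})

    tables = {}
    for stat in STATISTICS:
        df = pd.DataFrame(stat_rows[stat])
        path = os.path.join(out_dir, f"table_{stat}.csv")
        df.to_csv(path, index=False)
        tables[stat] = df
    pd.DataFrame(param_rows).to_csv(
        os.path.join(out_dir, "table_params.csv"), index=False)
    pd.DataFrame(long_rows).to_csv(
        os.path.join(out_dir, "table_scores_long.csv"), index=False)

    # pairwise Wilcoxon per ROI and statistic, voxel-wise pairing
    comparisons = []
    pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1:]]
    for roi_name, mask in rois.items():
        for stat in STATISTICS:
            for (ma, mb) in pairs:
                va = score_maps[f"{stat}_{ma}"][mask]
                vb = score_maps[f"{stat}_{mb}"][mask]
                ok = np.isfinite(va) & np.isfinite(vb)
                va, vb = va[ok], vb[ok]
                if va.size < 6:
                    continue
                try:
                    p = wilcoxon_signed_rank(va, vb)
                except UndefinedStatisticError:
                    p = float("nan")
                comparisons.append(ComparisonResult(
                    roi=roi_name, statistic=stat, model_a=ma, model_b=mb,
                    p_value=p, median_difference=float(np.median(va - vb)),
                    n_pairs=int(va.size)))
    comp_df = pd.DataFrame([{
        "roi": c.roi, "statistic": c.statistic, "model_a": c.model_a,
        "model_b": c.model_b, "p_value": c.p_value,
        "median_difference": c.median_difference, "n_pairs": c.n_pairs,
        "direction": c.direction,
    } for c in comparisons])
    comp_df.to_csv(os.path.join(out_dir, "table_comparisons.csv"), index=False)

    with open(os.path.join(out_dir, "run_log.txt"), "w") as fh:
        fh.write(f"dwidecay version: {_pkg_version}\n")
        fh.write(f"seed: {seed}\n")
        fh.write(f"models: {', '.join(models)}\n")
        fh.write(f"fit options: {opts}\n")
        fh.write(f"wilcoxon pairing: voxel-wise within ROI\n")
        fh.write(f"number of pairwise comparisons: {len(comparisons)} "
                 f"(no multiple-testing correction applied)\n")

    return {
        "param_maps": param_maps,
        "score_maps": score_maps,
        "summaries": summaries,
        "comparisons": comparisons,
        "tables": tables,
        "output_dir": out_dir,
        "rois": rois,
        "scheme": scheme,
    }
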