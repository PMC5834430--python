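# Methods

## The models

`dwidecay` models the direction-averaged, normalized diffusion-weighted
signal S(b)/S0 of a voxel as a sum of non-exchanging water compartments,
each attenuating mono-exponentially with its apparent diffusion
coefficient (ADC, mm²/s):

* **bi-exponential** (k = 3 free parameters)

      S/S0 = f_slow · e^(−ADC_slow·b) + f_fast · e^(−ADC_fast·b),
      f_slow + f_fast = 1

* **conventional tri-exponential** (k = 5)

      S/S0 = f_vs · e^(−ADC_vs·b) + f_slow · e^(−ADC_slow·b)
             + f_fast · e^(−ADC_fast·b),   f_vs + f_slow + f_fast = 1

* **modified tri-exponential** (k = 4)

      S/S0 = f0 + f_slow · e^(−ADC_slow·b) + f_fast · e^(−ADC_fast·b),
      f0 + f_slow + f_fast = 1

The modified model fixes one compartment's ADC at exactly zero: water
trapped in organelle-scale spaces attenuates so slowly that its signal is
effectively a constant floor `f0`, still visible at ultra-high b
(≥ 3000 s/mm²) where freely diffusing compartments have decayed away.
At b = 8000 s/mm² a compartment with ADC 500 × 10⁻⁶ mm²/s retains 1.8 % of
its signal and one with ADC 10 × 10⁻⁶ mm²/s retains 92.3 %, which is why
the ultra-high shell separates the hypotheses.

Conventions: ADCs are stored in mm²/s; the display unit 10⁻⁶ mm²/s appears
only in maps, summaries and serialized configs. Implied fractions
(`f_fast`) are always computed, never stored, so fractions sum to one
exactly. Free-parameter counts (3/5/4) exclude S0 because curves are
normalized to the measured b = 0 signal before fitting.

## Fitting

Each voxel's normalized curve is fitted by constrained least squares over
the b-values up to `fit_b_max` (default: all but the highest shell, i.e.
16 of the 17 b-values of the default scheme; the b = 8000 s/mm² shell is
held out for prediction). Constraints: fractions ≥ 0, fraction sums ≤ 1,
ADCs ≥ 0. Fits are label-swapped afterwards so ADCs ascend; degenerate
optima (equal ADCs) are flagged, not perturbed.

The optimizer works in scaled coordinates (b in 10³ s/mm², ADC in
10⁻³ mm²/s) so all parameters are O(1). It runs three stages:

1. **Projected spectral gradient descent** — Barzilai–Borwein step
   lengths with a backtracking (step-halving) line search and Euclidean
   projection of the fraction block onto {f ≥ 0, Σf ≤ 1} and of ADCs onto
   [0, ∞). Stops when the relative RSS decrease falls below `rel_tol`
   (default 10⁻⁹) or after `max_iterations` (default 10 000).
2. **Projected Levenberg–Marquardt refinement** — damped Gauss–Newton
   steps with the same projection; the descent stage alone converges only
   linearly in the thin curved valleys typical of exponential-sum
   fitting. Parameters pinned at the zero bound whose gradient points
   outward are handled as an active set (dropped from the Gauss–Newton
   system), otherwise the clipped coordinate corrupts the step for the
   free parameters and the iteration zigzags at the boundary.
3. **Deterministic multistart** — the same two stages from five fixed
   alternative starts (nested-model basin, slower/faster decay regimes, a
   spread start, and a zero-ADC basin), then one final descent+LM
   alternation from the best solution; the noisy objective is mildly
   multi-modal and projected LM alone can stall on an active constraint
   boundary.

Default initialization: f_slow = 0.50, ADC_slow = 600 × 10⁻⁶,
ADC_fast = 2000 × 10⁻⁶ mm²/s, plus f0 = 0.10 (modified) or
f_very_slow = 0.10 with ADC_very_slow = 100 × 10⁻⁶ mm²/s (conventional).

Correctness is anchored to `grid_oracle`, an exhaustive lattice search
over the feasible region (optionally LM-polished): on noisy curves the
production fit's RSS must never exceed the oracle's by more than 10⁻⁸,
and on noise-free curves every parameter is recovered to 0.1 %.

A `stability_experiment` mirrors the random-initialization protocol:
n init sets drawn uniformly from declared ranges (defaults
f0 ∈ [0.05, 0.10], f_slow ∈ [0.50, 0.60], ADC_slow ∈ [500, 800] × 10⁻⁶,
ADC_fast ∈ [1900, 2200] × 10⁻⁶), one fit per set, parameter distribution
returned. Because the fitter is effectively start-independent, the
resulting SDs are near zero — a stronger stability statement than a plain
fixed-step descent would give.

## Model ranking

Per voxel and model the package computes:

* **RSS** on the fitted points;
* **AICc** = 2k + N ln(RSS/N) + 2k(k+1)/(N−k−1), with N = 16 fitted
  points (b = 0 included; its residual is identically zero under the
  sum-to-one constraint) and k = 3/5/4. RSS below 10⁻³⁰ is floored with a
  warning before the logarithm (noise-free curves reach RSS = 0, where
  the criterion is undefined);
* **PRESS** — leave-one-out over the 16 fitted b-values, each refit
  starting from the default initialization so folds are independent; the
  b = 0 fold contributes exactly zero and stays in the cycle so the fold
  count matches N;
* **SPE** = (Sm − Sp)² at the held-out b = 8000 s/mm² shell, on the
  normalized scale; requesting a prediction at a fitted b-value is an
  error (information leak).

ROI aggregation: parameters as mean ± SD, ranking statistics as median
(q1, q3) with linear interpolation between order statistics. Pairwise
model comparisons use the two-sided Wilcoxon signed-rank test, paired
voxel-wise within an ROI (zero differences dropped; exact null for small
samples without ties, tie-corrected normal approximation otherwise; all
differences zero → reported undefined). No multiple-testing correction is
applied; the run log records the number of comparisons.

## The synthetic phantom

`synthetic_phantom` emulates the acquisition: 17 b-values from 0 to
8000 s/mm² with scan-average counts (1, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 5,
5, 5, 5, 9, 12), three orthogonal directions averaged at b > 0, and
magnitude (Rician) reconstruction. Each measurement is
|(S + g1) + i·g2| with g1, g2 ~ N(0, σ²); the scanner-style average of
nsa × 3 magnitudes shrinks the noise SD as 1/√(averages) but keeps each
sample's Rician bias — deliberately reproducing the positive noise floor
at ultra-high b that any zero-ADC analysis must contend with.

Default tissue classes (two-block geometry, WM block / GM block):

| class | model | f0 | f_slow | ADC_slow | ADC_fast | S0 (σ = 1) |
|-------|-------|------|--------|----------|----------|------------|
| WM | modified tri-exp | 0.15 | 0.55 | 600e-6 | 2000e-6 | 28.2 |
| GM | modified tri-exp | 0.02 | 0.60 | 800e-6 | 2200e-6 | 31.2 |

The S0 values make the per-average b = 0 SNR 28.2 (WM) and 31.2 (GM),
matching the difference-method SNR regime the acquisition targets; the
compartment values sit inside the ranges the protocol initializes and the
white/gray-matter contrast reported for f0 (substantial in WM, near zero
in GM). One seed governs the phantom; every voxel draws from a stream
spawned from (seed, flat index), so results never depend on traversal
order. The difference-method SNR estimator (mean of two repeats / SD of
their difference / √2) closes the loop: it recovers the known SNR within
10 % on a ≥ 500-voxel ROI.

### What the phantom does not emulate

Real brain data contain partial-volume mixing, anisotropy and
orientation dispersion, physiological fluctuation, motion/realignment
residuals and T2 differences between compartments. None are simulated.
The practical consequence, measured by the acceptance experiment: the
phantom's voxel RSS is thermal-noise dominated (~10⁻³ on the normalized
scale), an order of magnitude below in-vivo voxel RSS, so per-voxel AICc
contrasts between nested models are weaker here than in vivo. Passing
recovery and ranking tests on the phantom therefore validates the
estimator and statistics machinery, not the biological claim itself.

### Model ranking on the phantom, and a caution about optimizers

Under these conditions the bi-exponential model reliably fails the
held-out prediction in the WM class (highest SPE in ~75 % of voxels and
in the ROI median): without a zero-ADC compartment it must underpredict
the b = 8000 signal floor. The AICc contest between the two
tri-exponential variants is much tighter: with fitting run to
convergence, the conventional model's RSS is never above the modified
model's (it nests it via ADC_very_slow = 0), and its ROI-median AICc sits
within ~1 unit of the modified model's — the winner flips with the noise
realization. A plain fixed-step steepest-descent fitter, by contrast,
systematically stalls on the ill-conditioned 5-parameter model and can
report conventional tri-exponential RSS *above* the modified model's,
inverting that ranking. Reported AICc orderings between nested
exponential models are therefore partly a property of the optimizer, not
only of the data; this package always fits to convergence and documents
the consequence.

## Numerical choices

* RSS floor 10⁻³⁰ before the AICc logarithm.
* Quantiles: linear interpolation (numpy default).
* Simplex projection by bisection on the water-filling threshold.
* Tiny constraint violations from floating-point (≤ 10⁻¹⁵) are snapped
  back onto the feasible set after label swapping.
* Unfittable voxels (S0 ≤ 0, non-finite signals) become NaN in maps and
  are counted in the run log; ROI statistics ignore them.
* Problem sizes in the shipped experiments — 200 voxels per tissue class
  for ranking majorities, 50 curves for the oracle comparison, 100 for
  the PRESS bound, 625-voxel ROI for SNR — keep the full acceptance run
  in the tens of seconds while leaving Monte-Carlo error well inside the
  asserted margins.

## Known limitations

* Compartments are assumed non-exchanging and isotropic; no T2 weighting
  of fractions (f values are T2-weighted signal fractions, not volume
  fractions).
* The Rician floor biases fitted f0 upward in low-f0 tissue (measured:
  GM class truth 2 %, fitted mean ≈ 3.8 %); complex averaging, which
  would remove it, is not simulated.
* PRESS refits make leave-one-out expensive (16 refits per voxel per
  model); disable it (`include_press=False`, `--no-press`) when only
  AICc/SPE are needed.
* The Wilcoxon voxel-pairing treats voxels as exchangeable within an
  ROI; spatial correlation makes its p-values optimistic, as with any
  voxel-paired test.
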