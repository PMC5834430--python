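# dwidecay

Multi-b-value diffusion MRI decay modelling: detect the strictly
diffusion-limited water compartment in brain tissue.

## The problem

In diffusion-weighted imaging (DWI) the signal of freely diffusing water
decays as exp(−ADC·b). At ultra-high diffusion weighting
(b up to 8000 s/mm²) white-matter signal stops decaying and plateaus at
10–20 % of S0 — far above the noise floor. A compartment of water trapped
in organelle-scale spaces, with an apparent diffusion coefficient (ADC)
that is effectively **zero**, explains this floor. `dwidecay` implements
the three competing descriptions of the normalized signal S(b)/S0:

* bi-exponential: `f_slow·e^(−ADC_slow·b) + f_fast·e^(−ADC_fast·b)`
* conventional tri-exponential: adds a third free compartment
  `f_vs·e^(−ADC_vs·b)`
* **modified tri-exponential**:
  `f0 + f_slow·e^(−ADC_slow·b) + f_fast·e^(−ADC_fast·b)` — the zero-ADC
  compartment contributes the constant floor `f0`

together with constrained voxel-wise least-squares fitting, the
model-ranking stack (RSS, small-sample corrected AICc, leave-one-out
PRESS, squared prediction error SPE at a held-out b = 8000 s/mm² shell),
a Rician-noise synthetic phantom with known ground truth, and an
end-to-end pipeline producing ROI report tables. It is written for
researchers evaluating multi-compartment diffusion models on multi-b
acquisitions, and for testing such pipelines without scanner data.

## Worked example

Simulate one white-matter-like voxel under the default 17-b-value
acquisition (b = 0…8000 s/mm², scan averages 1…12, three directions,
magnitude reconstruction at SNR ≈ 28), then fit and rank the models:

```python
import numpy as np
import dwidecay as dw

scheme = dw.default_scheme()                     # 17 b-values, NSA schedule
wm = dw.default_wm_class()                       # f0=0.15, SNR 28.2 at b=0
raw = dw.acquire_voxel(wm, scheme, sigma=1.0,
                       rng=np.random.default_rng(0))

model = dw.ModifiedTriExponentialModel.from_signals(raw, scheme)
res = model.fit()
print(res.summary())
```

```
ModifiedTriExponentialModel fit
============================================
n fitted b-values                         16
free parameters (k)                        4
RSS                             1.587414e-03
AICc                                 -135.86
converged                               True
iterations                              3495
--------------------------------------------
f0 [%]                                 14.92
f_slow [%]                             67.18
f_fast [%]                             17.89
adc_slow [1e-6 mm2/s]                  685.4
adc_fast [1e-6 mm2/s]                 2782.5
============================================
```

The fit uses the first 16 b-values only; the b = 8000 s/mm² shell is held
out. The true floor (f0 = 15 %) is recovered as 14.92 % despite 3.5 % S0
noise. Ranking all three models on the same voxel:

```python
scores = dw.DecayModel.compare(model.curve, include_press=False)
for m in ("biexp", "triexp", "modtriexp"):
    print(f"{m:>10}: RSS={scores.rss[m]:.2e}  AICc={scores.aicc[m]:7.1f}"
          f"  SPE={scores.spe[m]:.2e}")
```

```
     biexp: RSS=2.15e-03  AICc= -134.7  SPE=3.47e-03
    triexp: RSS=1.59e-03  AICc= -131.5  SPE=1.82e-05
 modtriexp: RSS=1.59e-03  AICc= -135.9  SPE=1.75e-05
```

The bi-exponential model, lacking a zero-ADC compartment, underpredicts
the held-out ultra-high-b signal by two orders of magnitude in SPE; the
conventional tri-exponential matches the modified model's RSS (it nests
it) but pays the extra-parameter AICc penalty.

## Command line

```bash
dwidecay simulate --shape 32,32,4 --sigma 1.0 --seed 0 --out phantom/
dwidecay fit phantom/phantom.nii.gz --btable phantom/btable.txt \
         --model modtriexp --out maps/
dwidecay compare phantom/phantom.nii.gz --btable phantom/btable.txt \
         --out scores/
dwidecay report --config analysis.yaml
```

`report` runs the full pipeline (three model fits per voxel, ranking
maps, ROI median/quartile tables, pairwise Wilcoxon signed-rank
comparisons) from a YAML config; see
`dwidecay.pipeline.run_full_analysis` for the config keys.

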