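# freewater

Free-water elimination (FWE) for diffusion MRI, with the split-half
reliability machinery needed to evaluate it: bi-tensor model fitting for
multi-shell and single-shell acquisitions, free-water signal correction,
tensor-ODF reliability statistics (r², symmetric percent change), weighted
Dice overlap of tract-density maps, ICC(2,1) for tract profiles, streamline
utilities, and a synthetic phantom generator so the whole pipeline is
testable without scanner data.

## Who this is for

Diffusion-MRI researchers studying white matter in the presence of
free-water contamination — e.g. white-matter hyperintensities (WMH,
leukoaraiosis), where infiltrated cerebrospinal fluid inflates apparent
diffusivity and degrades both tensor metrics and tractography. FWE models
and removes the isotropic compartment so that orientation estimates and
tract reconstructions become more reproducible.

## The model

Each voxel's diffusion signal is a two-compartment mixture (the free-water
DTI model, FWDTI):

```
S(θ, b) = S0 (1 − f) exp(−b θᵀ Q θ) + S0 f exp(−b D_iso)
```

where `θ` is the gradient direction, `b` the diffusion weighting (s/mm²),
`Q` the tissue diffusion tensor (symmetric, 6 free parameters), `f` the
free-water volume fraction, and `D_iso = 3.0×10⁻³ mm²/s` the diffusivity of
free water at body temperature. Once `(S0, f, Q)` are estimated, the
free-water contribution is subtracted from every measurement:

```
S_fwe(θ, b) = S(θ, b) − S0 f exp(−b D_iso)
```

leaving a tissue-only residual signal.

Fitting comes in two regimes:

* **Multi-shell** (≥2 non-zero b-values): the model is well-posed per voxel
  and is fit by non-linear least squares (`MultiShellFreeWaterModel`),
  with the tensor parameterized through its Cholesky factor (always
  positive semi-definite) and `f` box-constrained to [0, 1].
* **Single-shell**: the per-voxel problem is ill-posed (`f` trades off
  against mean diffusivity), so the whole field is fit jointly
  (`SingleShellFreeWaterModel`): squared data residuals plus a spatial
  penalty on neighboring tensors, with `f` confined to a per-voxel
  feasibility interval derived from the observed attenuation. Descent
  directions are damped Gauss-Newton steps on the coupled system; the
  accepted cost sequence is non-increasing by construction.

Both estimators follow scikit-learn conventions: `fit(dataset)` produces a
fitted `field_`, `transform(dataset)` applies the free-water elimination.

Reliability of a pipeline is scored by splitting an acquisition randomly
and evenly into two halves at each b-value, running both halves through
identical processing, and comparing outputs: per-voxel Pearson r² between
tensor ODFs discretized on a 362-vertex sphere, weighted Dice between
tract-density maps, and ICC(2,1) between tract profiles.

## Worked example

```python
import numpy as np
from freewater import (simulate_phantom, fit_multishell,
                       run_split_half_experiment, compare_modes)

# simulate the reference acquisition (b = 500/1000/2500 s/mm² with
# 32/64/128 directions + 26 b0) over a phantom with NAWM (f=0.15),
# a WMH-like block (f=0.6) and a ventricle (f=1.0), Rician noise SNR 40
ds, truth, labels = simulate_phantom(shape=(20, 20, 5), snr=40.0, seed=7)

field = fit_multishell(ds)
for name, code in (("NAWM", 1), ("WMH", 2), ("ventricle", 3)):
    sel = labels == code
    print(f"{name:10s} true f = {truth.f[sel].mean():.2f}   "
          f"fitted f = {field.f[sel].mean():.3f} +/- {field.f[sel].std():.3f}")

cfg = {"dataset": {"shape": [20, 20, 5], "snr": 40.0, "seed": 7}, "split_seed": 11}
rep_fwe = run_split_half_experiment({**cfg, "mode": "fwe"})
rep_orig = run_split_half_experiment({**cfg, "mode": "original"})
gain = compare_modes(rep_fwe, rep_orig)
for region in ("nawm", "wmh"):
    print(f"{region}: median r2 fwe = {rep_fwe['regions'][region]['median_r2']:.3f}, "
          f"original = {rep_orig['regions'][region]['median_r2']:.3f}, "
          f"percent change = {gain['regions'][region]['percent_change_median_r2']:+.1f}%")
```

prints

```
NAWM       true f = 0.15   fitted f = 0.156 +/- 0.013
WMH        true f = 0.60   fitted f = 0.615 +/- 0.012
ventricle  true f = 1.00   fitted f = 0.978 +/- 0.001
nawm: median r2 fwe = 0.995, original = 0.993, percent change = +0.3%
wmh: median r2 fwe = 0.973, original = 0.890, percent change = +8.8%
```

The free-water fraction is recovered to ~0.01 in both tissue classes, and
free-water elimination raises split-half tensor-ODF reliability
substantially inside the high-free-water (WMH) region while leaving
normal-appearing white matter essentially unchanged — the qualitative
signature the method is designed to produce.

A command-line interface mirrors the library: `fwe simulate`, `fwe split`,
`fwe subshell`, `fwe fit`, `fwe reliability`, `fwe run` (see `fwe --help`).

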