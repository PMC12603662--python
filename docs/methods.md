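# Methods

## The bi-tensor (free-water DTI) model

A voxel's diffusion-weighted signal is modeled as a mixture of a Gaussian
anisotropic tissue compartment and an isotropic free-water compartment:

    S(θ, b) = S0 (1 − f) exp(−b θᵀQθ) + S0 f exp(−b D_iso)

* `Q` — symmetric 3×3 tissue diffusion tensor, stored as its 6 unique
  elements in lower-triangular order (xx, xy, yy, xz, yz, zz), mm²/s.
* `f` — free-water volume fraction, dimensionless, in [0, 1].
* `S0` — non-diffusion-weighted signal.
* `D_iso` — free-water diffusivity, default `3.0×10⁻³ mm²/s` (free water at
  body temperature); configurable on every entry point.

Free-water elimination subtracts the modeled isotropic term from each
measurement, `S_fwe = S − S0 f exp(−b D_iso)`. Under noise the corrected
signal can go negative; it is clipped at zero and the clip count logged,
because downstream tensor/ODF estimation requires non-negative signals.

Assumptions worth stating: a single Gaussian tissue compartment (crossing
fibers are not modeled by the tensor, though the corrected *signal* retains
their contributions), a fixed and known `D_iso`, and noise that is
approximately Gaussian at the fitted scale (the least-squares objective
ignores the Rician noise floor; at b0 SNR ≳ 20 the resulting bias in `f` is
small compared to the reported errors).

## Multi-shell fitting

With two or more non-zero shells the model is identifiable per voxel and is
fit by trust-region non-linear least squares, voxel-independently
(estimates are invariant to voxel ordering). Parameterization:

* `Q = L Lᵀ` through its lower-triangular factor, so iterates can never
  leave the PSD cone; internally tensors are scaled to µm²/ms so all
  unknowns are O(1).
* `f` enters directly with box bounds [0, 1] (trust-region-reflective);
  boundary values (`f = 0`, pure tissue) are attainable exactly.
* `S0` is optimized as a positive multiplier of the b0 mean.

Initialization: `S0` from the b0 mean; `Q` from a log-linear tensor fit on
the highest shell (eigenvalue-floored to PSD); `f` by mapping that fit's
apparent MD through the mixture relation assuming a tissue MD of
0.9×10⁻³ mm²/s (upper-typical white matter, so voxels with plausible tissue
MD start at the lower clamp), clamped to [0.01, 0.99]. Voxels with
non-positive b0 mean are flagged and excluded.

## Single-shell fitting

With one shell the per-voxel problem is ill-posed: `f` and the tensor's
isotropic part trade off along a nearly flat valley (measured: ~0.1% signal
change per Δf = 0.2 at b = 1000 s/mm²). Identification comes from two
added structures:

1. **Feasibility interval.** Per voxel, the mean shell attenuation
   `ā = mean(S/S0)` bounds `f` under assumed tissue diffusivities
   `D_t ∈ [0.1, 2.5]×10⁻³ mm²/s`:
   `f = (ā − exp(−b D_t)) / (exp(−b D_iso) − exp(−b D_t))` evaluated at the
   two diffusivity extremes, clipped to [0, 1]. `f` is optimized through a
   logistic transform confined to this interval.
2. **Spatial regularization.** The field cost is
   `Σ_v Σ_i (â_vi − a_vi)² + λ Σ_{v∼n} ‖Q'_v − Q'_n‖²_F`
   over in-mask voxels, shell measurements (attenuations `a = S/S0`, `S0`
   fixed at the b0 mean) and 6-neighbor pairs (tensors in µm²/ms).
   Default `λ = 0.03`, chosen by calibration on the reference phantom; it
   is deliberately weak — enough to pool tensor information across
   neighbors without erasing genuine boundaries. `λ = 0` recovers the
   (unstable) per-voxel problem and is supported for diagnostics.

**Optimizer.** Plain fixed-step gradient descent stalls in the flat valley
(after thousands of steps the fraction error is still ~0.15 on noiseless
data), so descent directions are damped Gauss-Newton steps on the full
coupled system: per-voxel 7×7 data blocks plus the sparse 6×6
neighbor-coupling blocks of the penalty, solved by conjugate gradients with
a block-Jacobi preconditioner. The Levenberg-Marquardt damping acts as the
adaptive step size: a trial step that raises the cost is rejected and
retried with tenfold damping, so the recorded cost sequence is
non-increasing by construction. Defaults: `max_iter = 150`; stop when the
relative cost decrease stays below `1e-8` for three consecutive accepted
steps (a single heavily damped micro-step must not read as convergence —
with a looser rule the optimizer halts long before the valley is
traversed). The logit of the normalized fraction is clipped to ±8 so
saturated voxels keep a usable gradient and can re-enter the interior.

On the reference phantom (20×20×5, b = 1000 + b0) this reaches mean
|f̂ − f| ≈ 2×10⁻⁴ noiseless and 0.02–0.05 at b0 SNR 40, at ~10–30 s on one
CPU.

## Reliability statistics

* **Spherical r².** Tensor ODFs, `ODF(u) ∝ (uᵀQ⁻¹u)^(−3/2)`, are sampled on
  a fixed, versioned, antipodally symmetric 362-vertex sphere (181
  golden-angle hemisphere points plus antipodes; bit-reproducible) and
  normalized to sum 1. Per voxel, the squared Pearson correlation between
  the two halves' 362-vectors. Constant vectors (isotropic ODFs) are
  undefined and propagate as NaN, counted in the QC block.
* **Symmetric percent change** between pipelines:
  `100 (r² − r²_ref) / (0.5 (r² + r²_ref))`; antisymmetric under swap,
  undefined when both inputs are zero.
* **Weighted Dice** of two density maps with normalized visitation weights
  `w = counts/Σcounts`:
  `Σ_{v∈supp(a)∩supp(b)} (w_a + w_b) / (Σ w_a + Σ w_b)`.
* **ICC(2,1)** — two-way random effects, absolute agreement, single rater —
  from the standard ANOVA mean squares, with listwise deletion of
  incomplete pairs; undefined below 3 complete pairs or at zero total
  variance. Verified against pingouin and a brute-force ANOVA oracle.

The tensor ODF stands in for spherical-deconvolution fODFs: the r² operator
applies to any discretized spherical function, and the tensor ODF gives the
pipeline a fully in-repo spherical field. This understates the reliability
gains that sharper fODF models would show, but preserves their direction.

## Split-half workflow

`run_split_half_experiment(config)` splits the acquisition randomly and
evenly at each b-value (seeded; odd shell counts give the extra measurement
to the first half), pushes both halves through one of two arms —
`original`: weighted log-linear tensor fit of the raw half; `fwe`:
free-water fit (multi-shell NLS or single-shell regularized, chosen by
shell count), elimination, then the same tensor fit on the corrected
signal — and correlates the halves' tensor ODFs per voxel. The tensor fit
is *weighted* log-linear (weights = observed signal): the log transform
gives low-signal measurements inflated influence, and unweighted LLS lets
their noise dominate exactly in the free-water-corrected arm the experiment
is about. Reports carry per-region medians, mean ± SEM over defined voxels,
QC counters, and the resolved config; runs are byte-deterministic given the
config seeds.

## Synthetic data

`make_scheme` builds acquisitions with electrostatically dispersed,
antipodally spread direction sets (deterministic given a seed) and evenly
interleaved b0 measurements; the default is the reference protocol
(b = 500/1000/2500 s/mm² with 32/64/128 directions, 26 b0 → 250
measurements). `simulate_voxel` generalizes the forward model to multiple
tissue compartments (for crossing-fiber voxels) and applies Rician noise:
`|signal + n₁ + i n₂|` with `n ~ N(0, S0/SNR)`, matching magnitude MRI; a
Gaussian option exists for debugging. `simulate_phantom` lays out
homogeneous labeled regions; defaults: NAWM background `f = 0.15`, a
WMH-like block `f = 0.6`, a ventricle `f = 1.0`, one shared prolate tissue
tensor with eigenvalues (1.7, 0.43, 0.43)×10⁻³ mm²/s (FA = 0.70,
MD = 0.85×10⁻³ mm²/s), `S0 = 100`, default b0 SNR 40, and an optional
orthogonal crossing region. The in-WMH fraction is a plausibility choice
(representative values are not established); it is config-exposed.

What the phantom does **not** emulate: anatomy and partial-volume
geometry, spatially varying S0 and coil profiles, fiber dispersion and
realistic crossing configurations, motion/eddy residuals, and
non-stationary noise. Passing tests therefore demonstrate correctness of
the estimators and statistics under the stated model, not performance on
clinical data.

## Tract utilities

Streamlines live in world (mm) coordinates (TCK I/O via nibabel). Density
maps count distinct streamlines per voxel, subdividing segments at half the
voxel size so corner-cutting segments register. Cleaning resamples to 100
nodes, measures each streamline's mean distance to the node-wise median
trajectory, and iteratively drops those more than 5 robust SDs
(1.4826×MAD, falling back to the plain SD when the MAD is zero) above the
median deviation; bundles under 20 streamlines pass through. Profiles
average a scalar map at 100 nodes with weights inverse to each node's
Mahalanobis distance from the node-wise bundle center (inverse-Euclidean
available); weights renormalize per node, so constant maps give constant
profiles regardless of geometry. Tract yield counts bundles with ≥10
streamlines. WMH overlap is the weighted Dice between a density map and a
uniformly weighted lesion mask.

## Numerical choices and degenerate inputs

* Shell assignment tolerance 50 s/mm² (scanner b-value jitter); b-values at
  or below the tolerance are b0.
* Signals are floored at 1e-6 before logs; log-linear fits are
  eigenvalue-floored at 1e-7 mm²/s before Cholesky factorization or ODF
  inversion.
* Singular/non-finite tensors are flagged per voxel and excluded from
  scalar maps and ODFs rather than poisoning summaries.
* Undefined statistics (constant ODFs, empty maps, degenerate ANOVA
  tables) propagate as NaN and are counted, never silently zeroed.
* Problem sizes in the test suite and acceptance script (20×20×5 phantom,
  300–1000 Monte-Carlo voxels per noise level) were chosen as the smallest
  sizes at which the Monte-Carlo summaries are stable across seeds.

## Known limitations

* Gaussian least-squares objectives on Rician data bias estimates at low
  SNR; no Rician likelihood option is provided.
* Single-shell estimates are regularization-dependent; `f` inside regions
  whose true tensors genuinely differ from their neighbors will be
  partially pooled.
* The ventricle (f = 1) leaves no tissue signal to correlate: post-FWE
  reliability there is noise, and the tensor within it is unidentifiable by
  construction.
* Tensor ODFs cannot represent crossing fibers; the crossing-region phantom
  is only used to verify that the *corrected signal* retains the two-tensor
  structure exactly.
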