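# Methods

`nlmpca` implements a two-stage restoration for 3D magnitude MR volumes:
an optimized blockwise 3D non-local means (NLM3D) filter followed by a
multilinear PCA (MPCA) truncation of the filtered slice stack.  This note
records the model, the conventions and defaults actually used, the design
choices that were genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Noise model and simulator

Magnitude MR noise is Rician: independent zero-mean Gaussian fields of
standard deviation σ corrupt the real and imaginary channels of the
signal, and the magnitude is taken,

    Y = sqrt((X + N₁)² + N₂²),  N₁, N₂ ~ N(0, σ²) i.i.d.

The simulator treats the clean magnitude as the real channel (imaginary
channel zero), draws the real field first and the imaginary field second
from one seeded generator, and is bit-reproducible for a fixed seed.  A
noise level of *p*% means σ = p/100 × a reference amplitude, by default
the maximum of the clean volume — the convention of the simulated-MRI
literature.  σ = 0 returns the input unchanged.

Consequences worth remembering: the noise is signal-dependent; in
zero-signal regions the observation is Rayleigh distributed with mean
σ·√(π/2) ≈ 1.25 σ, so *any* unbiased-averaging denoiser converges there
to a positive plateau, not to zero.  Neither stage performs Rician bias
correction (deliberately out of scope), so quality metrics on phantoms
with a large background are floored by this bias for every method alike.

## Phantom generator

The generator emulates a T1-weighted head acquisition without external
data.  A two-octave Gaussian random field (coarse component blurred at
1/8 of the smallest axis for lobe-scale regions, fine component at 1/24
for gyral-scale convolutions, mixed 0.7/0.3 after z-scoring) is added to
a centred ellipsoidal gradient, and the result is thresholded at fixed
quantiles: the lowest 35% of field values become background (intensity
0) and the remaining classes split the rest equally, so every declared
class occupies a macroscopic share of the volume.  Default intensities
(0, 45, 105, 165, 255) stand for background, CSF, grey matter, white
matter and scalp/fat on a 0–255 scale.  A Gaussian blur of 1.2 voxels
FWHM (default) models partial-volume averaging at tissue interfaces;
with the blur disabled the phantom is exactly piecewise-constant.

What the phantom does *not* reproduce: true cortical topology, intensity
inhomogeneity (bias fields), spatially varying or correlated noise, and
the full 181×217×181 extent of a real acquisition.  Experiments here run
at 64³, so surface shells occupy a far larger voxel fraction than at
clinical resolution; results are qualitative orderings, not clinical
effect sizes.

## Stage 1 — blockwise 3D non-local means

Cubic blocks of half-width *p* (the patch radius, default 2) centred on a
stride-*s* grid (default 2; the last in-volume index is appended per axis
so every voxel is covered) are each restored as a normalised
exponentially weighted average of all candidate blocks whose centres lie
in the cubic search volume of half-width *R* (default 5) clipped to the
volume:

    ŵ(i,j) = exp(−d(Nᵢ, Nⱼ)/h²),   w(i,j) = ŵ(i,j)/Σⱼ ŵ(i,j)

so weights lie in [0, 1] and sum to one at every reference block.  The
patch distance d is the squared Euclidean distance divided by the patch
voxel count; patches reaching past the boundary are completed by
mirror reflection, while candidate *centres* are never invented outside
the volume.  Each voxel's output is the arithmetic mean of every block
estimate covering it.  Output values are convex combinations of input
values (range preservation), and adding a constant to the input shifts
the output by exactly that constant.

Numerical conventions:

* **Bandwidth.** h² = 2·β·σ̂² with β = 1 against the normalised distance
  (equivalently 2βσ̂²·|N| against the unnormalised one, the optimized
  blockwise-NLM convention).  σ̂ is estimated from high-frequency
  pseudo-residuals — √(6/7)·(x − mean of 6 face neighbours), robustified
  by 1.4826·MAD — unless supplied.  On a noise-free volume σ̂ = 0 and h
  degenerates to a strictly positive epsilon, making the filter
  (near-)identity on structured patches.  The MAD estimator overshoots
  the nominal σ by ~10–15% on Rician phantoms (edges and the Rayleigh
  background contaminate the residuals); this is accepted rather than
  hidden behind an ad-hoc correction.
* **Self-weight.** The centre's raw weight exp(0) = 1 is capped at the
  largest raw weight among the other candidates by default (standard
  guard against over-weighting the noisy centre); the literal exp(0)
  behaviour is selectable and both fix constant volumes exactly.
* **Preselection.** A mean-ratio pretest (skip candidates whose patch
  mean falls outside [0.5, 2]× the reference mean) exists but is off by
  default so results match the literal formula.
* The fast implementation reorganises the computation per search offset
  (distance fields by a box filter of squared shifted differences,
  weight spreading by box sums) and is verified to 10⁻¹⁰ against a
  literal triple-loop implementation on seeded volumes.

## Stage 2 — multilinear PCA truncation

The volume is the slice set {X₁, …, X_M}, X_m ∈ R^{I1×I2}, M = I3.  MPCA
seeks orthonormal per-mode bases U⁽¹⁾, U⁽²⁾ maximising the total scatter
Ψ = Σ_m ‖Y_m − Ȳ‖²_F of the projected slices Y_m = U⁽¹⁾ᵀ X_m U⁽²⁾.  The
fit alternates over the two in-plane modes, setting each basis to the
eigenvectors (descending eigenvalue order) of that mode's scatter matrix
of the centred, other-mode-projected slices.  With full square bases an
orthonormal projection along the other mode leaves a mode's scatter
unchanged, so the first pass is already optimal and the iteration
(max 5 passes, relative tolerance 10⁻⁶ on the captured top-K scatter)
exits at pass 2; the loop is kept because it is the general algorithm.
Eigenvector signs are fixed by making each column's largest-magnitude
entry positive, so fits are reproducible across eigensolvers.  The slice
axis is never projected: slices are the samples.

Denoising keeps the leading K eigenvectors per mode (K clipped per mode
to that mode's dimension) and projects each slice's rows and columns
onto those subspaces.  Properties enforced by tests: projectors are
idempotent; reconstruction error is nonincreasing in K; the one-sided
projection error on centred slices equals the discarded eigenvalue tail
of its mode; and K = max(I1, I2) — full rank in *both* modes after
per-mode clipping — is the exact identity.  (For non-square slices,
K = min(I1, I2) is *not* the identity: a rank-min projector on the larger
mode necessarily discards energy.  The per-mode clipping rule is the
mathematically consistent reading of "one K for both modes".)

**Centering.** The truncated reconstruction is applied to the *raw*
slice by default, exactly as the formula is usually printed.  This is
degenerate when all slices are (nearly) identical: the centred scatter
is then zero, the basis arbitrary, and the raw projection far from
identity — a constant volume does not survive the default MPCA stage.
The `recenter` option (project the centred slice, add the mean back) is
exact in that case and available everywhere; measured quality on
phantoms is indistinguishable between the two, so the printed formula
remains the default.

## Pipeline

Default order: NLM3D first, MPCA fitted *on the NLM output* and applied
with K (default 140, the reference setting for a 181×217×181 volume;
clipped per mode at run time).  The reverse order is supported for the
stage-order experiment.  All stage parameters — including the automatic
h — are resolved once against the pipeline input, logged, and shared by
both orders, so a run is exactly replayable from its log line and the
order comparison is not confounded by different bandwidths.

## Scaled-down experiments

The acceptance experiment uses 64³ phantoms, 5% noise and K = 53 (the
reference optimum band 140–160 of a 181-dim mode, scaled to 64), three
replicate phantoms, chosen so the whole run completes in minutes on one
CPU.  Findings the tests assert:

* the NLM stage, the two-stage pipeline and the reversed order all
  improve PSNR over the noisy input;
* NLM-then-MPCA beats MPCA-then-NLM (truncating the noisy volume first
  loses detail the subsequent NLM cannot recover).

A limitation the tests expose rather than hide: at this scale the MPCA
stage after NLM is PSNR-neutral-to-slightly-negative (−0.02 dB).  With
β = 1 the NLM stage averages hundreds of patches and leaves a white
residual of std ≈ 0.7 intensity units, so the NLM output holds ~39k
units² of energy in the discarded subspace against ~1.3M units² of
clean-signal energy there: truncation has essentially no noise left to
remove at any nontrivial K (the K-sweep is monotone in K).  A weaker
first stage or richer data is needed for the second stage to add
measurable PSNR; the corresponding acceptance test is left failing as an
honest record of this behaviour at desk scale.

## Known limitations

* No Rician bias correction; background plateaus at σ√(π/2).
* Metrics default to peak = L = 255 and are computed over the whole
  volume (no foreground masking).
* Global SSIM (the single-formula variant) is the default; the windowed
  variant (7³ windows, sample statistics, interior windows only) matches
  scikit-image's uniform-window implementation exactly and is available
  via `mode="windowed"`.
* The NLM implementation requires every axis to be at least
  search_radius + patch_radius + 1 voxels.
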