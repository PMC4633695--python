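# nlmpca — two-stage 3D MRI denoising

Thermal noise in magnitude MR images is Rician: Gaussian fluctuations on
the real and imaginary channels become a signal-dependent, nonnegative
perturbation after the magnitude operation, degrading any quantitative
measurement taken from the volume.  `nlmpca` restores noisy 3D T1-style
volumes in two passes, for researchers who want a transparent, fully
tested reference implementation of the approach rather than a black box:

1. **Blockwise 3D non-local means (NLM3D).**  Overlapping cubic blocks on
   a subsampled grid are each restored as a weighted average of the
   blocks in their search volume Ω,

       x̂(B_i) = Σ_{j∈Ω} w(i,j) · B_j,
       w(i,j) = Z(i)⁻¹ · exp(−d(N_i, N_j)/h²),   Σ_j w(i,j) = 1,

   where d(N_i, N_j) is the (voxel-normalised) squared Euclidean distance
   between the cubic intensity patches around i and j, and every voxel's
   output is the mean of the block estimates covering it.
2. **Multilinear PCA (MPCA) truncation.**  The filtered volume is a slice
   set {X_1, …, X_M}; per-mode orthonormal bases U⁽¹⁾, U⁽²⁾ maximise the
   total scatter Ψ = Σ_m ‖Y_m − Ȳ‖²_F of the projections
   Y_m = U⁽¹⁾ᵀ X_m U⁽²⁾ (eigenbases of the mode scatter matrices), and
   each slice is reconstructed from the leading K components per mode,

       X̄_m = Ū⁽¹⁾ᵀ Ū⁽¹⁾ X_m Ū⁽²⁾ᵀ Ū⁽²⁾,

   discarding the noise-dominated tail.

The package also ships the Rician noise simulator, a seeded brain-like
phantom generator (so everything is testable without downloads), the
SNR/PSNR/SSIM/RMSE quality metrics, a K-sweep and stage-order experiment
driver, NIfTI-1 I/O, and a CLI.  See `docs/methods.md` for conventions,
defaults and limitations.

## Worked example

```python
import nlmpca as m

clean = m.generate_phantom(m.PhantomSpec(shape=(48, 48, 48), seed=7))
noisy = m.add_rician_noise(clean, m.NoiseSpec(percent=5.0, seed=8))
config = m.PipelineConfig(k=40)          # components kept per in-plane mode
denoised = m.denoise_two_stage(noisy, config)

print("noisy   :", m.evaluate(clean, noisy).to_text().replace("\n", "  "))
print("denoised:", m.evaluate(clean, denoised).to_text().replace("\n", "  "))
```

prints

```
noisy   : snr_db=15.931509046876545  psnr_db=24.907473900285538  rmse=14.493273421303389  ssim=0.9869717086588607  dynamic_range_L=255.0
denoised: snr_db=16.600524308525205  psnr_db=25.57648916193419  rmse=13.41886310368252  ssim=0.9886298335619602  dynamic_range_L=255.0
```

i.e. on a 48³ five-class phantom with 5% Rician noise the pipeline gains
about 0.7 dB SNR/PSNR and lowers the RMSE from 14.5 to 13.4 intensity
units.  (Absolute numbers are floored by the Rician background bias —
zero-signal regions plateau at σ√(π/2) for any averaging denoiser; see
the methods note.)

The same run from the shell:

```sh
nlmpca simulate phantom --shape 48 48 48 --seed 7 -o clean.nii.gz
nlmpca simulate noise --percent 5 --seed 8 -i clean.nii.gz -o noisy.nii.gz
nlmpca denoise pipeline -i noisy.nii.gz -o out.nii.gz --k 40
nlmpca metrics -r clean.nii.gz -t out.nii.gz
```

`nlmpca denoise nlm3d` and `nlmpca denoise mpca` run single stages;
`nlmpca experiment ksweep` tabulates SNR/PSNR/SSIM against the truncation
rank K as CSV.

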