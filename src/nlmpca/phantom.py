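"""Synthetic brain-like phantoms and Rician noise simulation.

The phantom generator produces a piecewise-homogeneous volume with a small
number of tissue classes arranged as nested smooth blobs, mimicking the
geometry of a T1-weighted brain acquisition (background, CSF, grey matter,
white matter, scalp/fat) without requiring any external data.  Regions are
the level sets of a seeded low-frequency Gaussian random field combined
with a centred ellipsoidal gradient, thresholded at fixed quantiles, so
every volume has curved class boundaries and large flat interiors — the
two features patch-based denoisers exploit.

Rician noise is simulated the way magnitude MR noise arises physically:
independent zero-mean Gaussian fields of standard deviation sigma are added
to the real and imaginary channels of the (real-valued) clean signal and
the magnitude is taken::

    noisy = sqrt((clean + n1)**2 + n2**2),   n1, n2 ~ N(0, sigma^2)

sigma is expressed as a percentage of a reference amplitude, by default the
maximum of the clean volume (the convention of the simulated-MRI
literature, where "p% noise" means sigma = p/100 * peak intensity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "generate_phantom",
    "add_rician_noise",
    "DEFAULT_CLASS_INTENSITIES",
]

# Background, CSF, grey matter, white matter, scalp/fat on a 0-255 scale.
DEFAULT_CLASS_INTENSITIES = (0.0, 45.0, 105.0, 165.0, 255.0)

# Fraction of the volume occupied by the lowest (background) class; the
# remaining classes share the rest equally.  Head-in-air acquisitions have
# a large empty background.
_BACKGROUND_FRACTION = 0.35

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a deterministic piecewise-homogeneous phantom.

    Attributes
    ----------
    shape
        Voxel counts per axis; each must be >= 8.
    class_intensities
        Strictly increasing nonnegative intensities, one per tissue class,
        with the background class at intensity 0.  Length >= 2.
    smoothing_fwhm
        Full width at half maximum, in voxels, of an optional Gaussian blur
        applied to the labelled volume (0 disables it).  Smoothing models
        partial-volume averaging at tissue interfaces.
    seed
        RNG seed; identical spec + seed gives a bit-identical phantom.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    class_intensities: tuple[float, ...] = DEFAULT_CLASS_INTENSITIES
    smoothing_fwhm: float = 1.2  # mild partial-volume averaging at interfaces
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_intensities)

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(f"phantom shape entries must be >= 8, got {self.shape}")
        ci = np.asarray(self.class_intensities, dtype=float)
        if ci.size < 2:
            raise ValueError("need at least 2 tissue classes")
        if not np.all(np.isfinite(ci)) or np.any(ci < 0):
            raise ValueError("class intensities must be finite and nonnegative")
        if np.any(np.diff(ci) <= 0):
            raise ValueError("class intensities must be strictly increasing")
        if ci[0] != 0.0:
            raise ValueError("background class intensity must be 0")
        if not np.isfinite(self.smoothing_fwhm) or self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be a nonnegative real")


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise level.

    ``percent`` is the noise standard deviation as a percentage of
    ``reference_amplitude``; ``reference_amplitude="auto"`` uses the maximum
    of the clean volume.
    """

    percent: float = 5.0
    reference_amplitude: float | str = "auto"
    seed: int = 0

    def validate(self) -> None:
        if not np.isfinite(self.percent) or not 0.0 <= self.percent <= 100.0:
            raise ValueError(f"noise percent must lie in [0, 100], got {self.percent}")
        if self.reference_amplitude != "auto":
            ref = float(self.reference_amplitude)  # type: ignore[arg-type]
            if not np.isfinite(ref) or ref <= 0:
                raise ValueError("reference_amplitude must be positive or 'auto'")

    def sigma(self, clean: np.ndarray) -> float:
        """Absolute noise standard deviation for a given clean volume."""
        self.validate()
        if self.reference_amplitude == "auto":
            ref = float(np.max(clean))
            if ref <= 0:
                ref = 1.0  # all-zero volume: fall back to unit amplitude
        else:
            ref = float(self.reference_amplitude)  # type: ignore[arg-type]
        return self.percent / 100.0 * ref


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Generate a deterministic piecewise-homogeneous 3D phantom.

    The label field is built from ``0.5 * z-scored low-frequency Gaussian
    field + ellipsoidal radial gradient`` thresholded at fixed quantiles:
    the background class takes the lowest 35% of field values and the
    remaining classes split the rest equally, so every class occupies a
    macroscopic share of the volume.  Before smoothing, voxel values are
    exactly the class intensities.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)

    # Two-octave random field: a coarse component (~1/8 of the smallest
    # axis) shapes lobe-scale regions and a fine component (~1/24) adds
    # gyral-scale convolutions, mirroring the multi-scale anatomy of a T1
    # head.  The coarse field is drawn first, then the fine one, so the
    # output is reproducible.  Each component is z-scored before mixing.
    def zscored_field(blur_sigma: float) -> np.ndarray:
        f = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=blur_sigma, mode="reflect"
        )
        return (f - f.mean()) / max(f.std(), np.finfo(float).tiny)

    coarse = zscored_field(max(min(shape) / 8.0, 2.0))
    fine = zscored_field(max(min(shape) / 24.0, 1.0))
    field = 0.7 * coarse + 0.3 * fine

    # Centred ellipsoidal gradient (1 at the centre, ~ -1 at the corners)
    # nests the level sets: high classes central, background peripheral.
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij", sparse=True
    )
    radial = 1.0 - 2.0 * sum(g**2 for g in grids) / 3.0
    field = 0.5 * field + radial

    n = spec.n_classes
    inner = np.linspace(0.0, 1.0, n)[1:-1]  # interior class boundaries
    qs = _BACKGROUND_FRACTION + (1.0 - _BACKGROUND_FRACTION) * inner
    thresholds = np.quantile(field, np.concatenate(([_BACKGROUND_FRACTION], qs)))
    labels = np.searchsorted(thresholds, field, side="right")
    data = np.asarray(spec.class_intensities, dtype=np.float64)[labels]

    if spec.smoothing_fwhm > 0:
        # mode="nearest" keeps the blur a convex combination of volume
        # values, so the output stays inside [min, max] of the classes.
        data = ndimage.gaussian_filter(
            data, sigma=spec.smoothing_fwhm * _FWHM_TO_SIGMA, mode="nearest"
        )
        data = np.clip(data, spec.class_intensities[0], spec.class_intensities[-1])

    return Volume(data=data, intensity_units="arbitrary (0-peak)")


def add_rician_noise(clean: Volume, noise: NoiseSpec) -> Volume:
    """Corrupt a clean magnitude volume with Rician noise.

    The clean magnitude is taken as the real channel (imaginary channel 0);
    the real noise field is drawn first, then the imaginary one, so the
    output is reproducible for a fixed seed.  ``sigma == 0`` returns the
    input data unchanged (the magnitude of a nonnegative real is itself).
    """
    sigma = noise.sigma(clean.data)
    if sigma == 0.0:
        return clean.with_data(clean.data.copy())
    rng = np.random.default_rng(noise.seed)
    n_real = rng.normal(0.0, sigma, size=clean.shape)
    n_imag = rng.normal(0.0, sigma, size=clean.shape)
    noisy = np.hypot(clean.data + n_real, n_imag)
    return clean.with_data(noisy)
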