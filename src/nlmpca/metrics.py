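"""Volume-pair quality measures: SNR, PSNR, RMSE and SSIM.

All four are computed between a reference (clean) volume ``x`` and a test
(denoised) volume ``x~`` of equal shape:

* SNR  = 10 log10( sum (x - xbar)^2 / sum (x - x~)^2 ),  xbar the reference
  mean — reference variance over residual energy, in dB.
* RMSE = sqrt( mean (x - x~)^2 ).
* PSNR = 20 log10( peak / RMSE ), peak defaulting to 255.
* SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
         / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)),
  c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03, L the dynamic range.

SSIM is evaluated globally by default — one application of the formula to
whole-volume means, variances and covariance — with a windowed mode (mean
of the formula over every fully interior sliding cubic window, sample
statistics) available for comparison with windowed implementations.

Identical inputs give RMSE 0, SSIM exactly 1, and the PSNR/SNR infinities
are reported as ``math.inf`` (serialised as the string ``"inf"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["QualityReport", "rmse", "snr", "psnr", "ssim", "evaluate"]

K1 = 0.01
K2 = 0.03


def _pair(
    reference: Volume | np.ndarray, test: Volume | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    x = reference.data if isinstance(reference, Volume) else np.asarray(reference)
    y = test.data if isinstance(test, Volume) else np.asarray(test)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: reference {x.shape} vs test {y.shape}")
    return x, y


def rmse(reference: Volume | np.ndarray, test: Volume | np.ndarray) -> float:
    """Root mean squared voxel difference."""
    x, y = _pair(reference, test)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def snr(reference: Volume | np.ndarray, test: Volume | np.ndarray) -> float:
    """Signal-to-noise ratio in dB; ``inf`` for identical inputs."""
    x, y = _pair(reference, test)
    num = float(np.sum((x - x.mean()) ** 2))
    if num == 0.0:
        raise ValueError("constant reference: SNR numerator is zero")
    den = float(np.sum((x - y) ** 2))
    if den == 0.0:
        return math.inf
    return 10.0 * math.log10(num / den)


def psnr(
    reference: Volume | np.ndarray, test: Volume | np.ndarray, peak: float = 255.0
) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical inputs."""
    if not peak > 0:
        raise ValueError("peak must be positive")
    err = rmse(reference, test)
    if err == 0.0:
        return math.inf
    return 20.0 * math.log10(peak / err)


def ssim(
    reference: Volume | np.ndarray,
    test: Volume | np.ndarray,
    L: float = 255.0,
    mode: str = "global",
    window: int = 7,
) -> float:
    """Structural similarity index, in [-1, 1]; 1 iff inputs identical.

    ``mode="global"`` applies the formula once to whole-volume statistics
    (population variances).  ``mode="windowed"`` averages the formula over
    every sliding cubic window of side ``window`` that lies fully inside
    the volume, using sample (N-1) variances — the convention of common
    windowed SSIM implementations.
    """
    x, y = _pair(reference, test)
    if not L > 0:
        raise ValueError("dynamic range L must be positive")
    c1 = (K1 * L) ** 2
    c2 = (K2 * L) ** 2
    if mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = float(np.mean((x - mx) * (y - my)))
        return float(
            (2 * mx * my + c1)
            * (2 * cxy + c2)
            / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    if mode != "windowed":
        raise ValueError(f"mode must be 'global' or 'windowed', got {mode!r}")
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if min(x.shape) < window:
        raise ValueError(f"volume smaller than the {window}^3 window")
    pad = window // 2
    interior = tuple(slice(pad, s - pad) for s in x.shape)

    def win_mean(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=window, mode="constant")[interior]

    n = window**3
    bessel = n / (n - 1.0)
    mx, my = win_mean(x), win_mean(y)
    vx = (win_mean(x * x) - mx**2) * bessel
    vy = (win_mean(y * y) - my**2) * bessel
    cxy = (win_mean(x * y) - mx * my) * bessel
    s = (2 * mx * my + c1) * (2 * cxy + c2) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    return float(s.mean())


@dataclass
class QualityReport:
    """Bundle of the four quality measures for one volume pair."""

    snr_db: float
    psnr_db: float
    rmse: float
    ssim: float
    dynamic_range_L: float
    k1: float = K1
    k2: float = K2

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range_L) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range_L) ** 2

    def as_dict(self) -> dict[str, float | str]:
        """Flat serialisable mapping; infinities become the string 'inf'."""
        out: dict[str, float | str] = {}
        for key in ("snr_db", "psnr_db", "rmse", "ssim", "dynamic_range_L"):
            v = getattr(self, key)
            out[key] = "inf" if math.isinf(v) else float(v)
        return out

    def to_text(self) -> str:
        return "\n".join(f"{k}={v}" for k, v in self.as_dict().items())


def evaluate(
    reference: Volume | np.ndarray,
    test: Volume | np.ndarray,
    peak: float = 255.0,
    L: float = 255.0,
    ssim_mode: str = "global",
) -> QualityReport:
    """Compute SNR, PSNR, RMSE and SSIM consistently for one pair."""
    return QualityReport(
        snr_db=snr(reference, test),
        psnr_db=psnr(reference, test, peak=peak),
        rmse=rmse(reference, test),
        ssim=ssim(reference, test, L=L, mode=ssim_mode),
        dynamic_range_L=float(L),
    )
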