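"""Quantitative evaluation of reconstructions against ground truth.

Two gauge freedoms of Fourier ptychography are removed before any
comparison, since neither is observable from intensity data:

* **global phase** — a constant phase of the recovered field;
* **tilt / shift** — a linear pupil phase is exactly equivalent to a lateral
  shift of the object (the per-frame constant phases it also induces drop
  out of the intensities), so the reconstruction splits a tilt aberration
  arbitrarily between a shifted object and a tilted pupil.  Evaluation picks
  the gauge that registers the recovered object to the reference, and moves
  the corresponding linear ramp into the pupil.

RMSE follows the common benchmarking convention for reconstructed images:
both amplitudes are min-max normalised to [0, 1] first; phase maps are
compared after removing the mean phase difference, scaled by the known
ground-truth phase range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from numpy.fft import fft2, ifft2
from scipy.ndimage import fourier_shift, map_coordinates
from skimage.metrics import structural_similarity
from skimage.registration import phase_cross_correlation
from skimage.restoration import unwrap_phase

from .forward import Pupil
from .geometry import FrequencyGrid
from .zernike import (wavefront_from_coeffs, unit_disk_coordinates,
                      ZernikeCoefficients)

__all__ = [
    "MetricsReport", "rmse_image", "ssim_image", "line_profile",
    "align_to_truth", "shift_pupil_tilt", "recovered_pupil_phase",
]


@dataclass
class MetricsReport:
    """One row of a benchmark table."""

    algorithm: str
    amplitude_rmse: float
    phase_rmse: float
    pupil_phase_ssim: float
    iterations: int
    final_error: float
    runtime_seconds: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @staticmethod
    def csv_header() -> str:
        return ("algorithm,amplitude_rmse,phase_rmse,pupil_phase_ssim,"
                "iterations,final_error,runtime_seconds")

    def to_csv_row(self) -> str:
        return (f"{self.algorithm},{self.amplitude_rmse:.6g},"
                f"{self.phase_rmse:.6g},{self.pupil_phase_ssim:.6g},"
                f"{self.iterations},{self.final_error:.6g},"
                f"{self.runtime_seconds:.4g}")


# ----------------------------------------------------------------------
# scalar image metrics
# ----------------------------------------------------------------------
def _minmax(im: np.ndarray) -> np.ndarray:
    rng = im.max() - im.min()
    if rng == 0:
        return np.zeros_like(im)
    return (im - im.min()) / rng


def rmse_image(estimate: np.ndarray, truth: np.ndarray,
               mode: str = "amplitude") -> float:
    """Root-mean-square error between a reconstruction and its reference.

    ``amplitude``: both images are min-max normalised to [0, 1] first.
    ``phase``: the mean phase difference (unobservable global phase) is
    subtracted, then the residual is scaled by the ground-truth phase range
    so the value is comparable to the normalised amplitude RMSE.
    """
    estimate = np.asarray(estimate, float)
    truth = np.asarray(truth, float)
    if estimate.shape != truth.shape:
        raise ValueError("shape mismatch")
    if mode == "amplitude":
        d = _minmax(estimate) - _minmax(truth)
    elif mode == "phase":
        # wrap the pointwise difference into (-pi, pi] before removing the
        # mean, so a reconstruction straddling the +/-pi branch cut is not
        # penalised for the unobservable global phase
        d = np.angle(np.exp(1j * (estimate - truth)))
        d = d - d.mean()
        rng = truth.max() - truth.min()
        d = d / rng if rng > 0 else d
    else:
        raise ValueError("mode must be 'amplitude' or 'phase'")
    return float(np.sqrt(np.mean(d ** 2)))


def ssim_image(estimate: np.ndarray, truth: np.ndarray,
               support: np.ndarray | None = None) -> float:
    """Mean local structural similarity (Gaussian window 11, sigma 1.5).

    With ``support`` given (e.g. the pupil disk), the SSIM map is averaged
    over supported pixels only.
    """
    estimate = np.asarray(estimate, float)
    truth = np.asarray(truth, float)
    if estimate.shape != truth.shape:
        raise ValueError("shape mismatch")
    lo = min(estimate.min(), truth.min())
    hi = max(estimate.max(), truth.max())
    data_range = hi - lo if hi > lo else 1.0
    _, ssim_map = structural_similarity(
        truth, estimate, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=data_range, full=True)
    if support is None:
        return float(ssim_map.mean())
    return float(ssim_map[support].mean())


def line_profile(image: np.ndarray, start: tuple[float, float],
                 end: tuple[float, float]) -> np.ndarray:
    """Min-max normalised bilinear samples along a segment (row, col coords).

    The profile has ``round(length) + 1`` samples; a constant image returns
    the neutral value 0.5 everywhere.
    """
    image = np.asarray(image, float)
    r0, c0 = start
    r1, c1 = end
    for r, c in (start, end):
        if not (0 <= r <= image.shape[0] - 1 and 0 <= c <= image.shape[1] - 1):
            raise ValueError("profile endpoints must lie inside the image")
    length = float(np.hypot(r1 - r0, c1 - c0))
    n = int(round(length)) + 1
    if n < 2:
        raise ValueError("degenerate (zero-length) profile segment")
    t = np.linspace(0.0, 1.0, n)
    coords = np.vstack([r0 + t * (r1 - r0), c0 + t * (c1 - c0)])
    vals = map_coordinates(image, coords, order=1)
    rng = vals.max() - vals.min()
    if rng == 0:
        return np.full(n, 0.5)
    return (vals - vals.min()) / rng


# ----------------------------------------------------------------------
# gauge fixing
# ----------------------------------------------------------------------
def align_to_truth(field_est: np.ndarray, field_truth: np.ndarray,
                   upsample: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Register the recovered complex field to the reference.

    Returns the sub-pixel-shifted, global-phase-corrected field and the
    applied (row, col) shift in pixels.  The shift is estimated from the
    amplitudes by upsampled phase cross-correlation.
    """
    shift, _, _ = phase_cross_correlation(
        np.abs(field_truth), np.abs(field_est), upsample_factor=upsample,
        normalization=None)
    aligned = ifft2(fourier_shift(fft2(field_est), shift))
    gamma = np.angle(np.sum(aligned * np.conj(field_truth)))
    return aligned * np.exp(-1j * gamma), shift


def shift_pupil_tilt(pupil: Pupil, shift_px: np.ndarray, n_hr: int) -> Pupil:
    """Move the linear (tilt) gauge ramp of an object shift into the pupil.

    A recovered object displaced by ``-shift_px`` pixels relative to the
    reference corresponds to a pupil carrying the ramp
    ``exp(-2 pi i (p . shift) / n_hr)`` over frequency pixels ``p``;
    multiplying by the inverse ramp restores the tilt to the pupil so it can
    be compared with, or decomposed against, the true wavefront.
    """
    n = pupil.values.shape[0]
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    ramp = 2 * np.pi * ((yy - c) * shift_px[0] + (xx - c) * shift_px[1]) / n_hr
    return Pupil(values=pupil.values * np.exp(1j * ramp), support=pupil.support)


def recovered_pupil_phase(pupil: Pupil) -> np.ndarray:
    """Unwrapped, piston-removed pupil phase (radians) on the support.

    Phase unwrapping runs on the masked disk so 2-pi wraps inside strongly
    aberrated pupils do not corrupt comparisons; the mean over the support
    (piston, an unobservable global phase) is removed.  Pixels outside the
    support are zero.
    """
    masked = np.ma.array(pupil.phase, mask=~pupil.support)
    un = np.asarray(unwrap_phase(masked).filled(0.0))
    mean = un[pupil.support].mean() if pupil.support.any() else 0.0
    out = np.where(pupil.support, un - mean, 0.0)
    return out


def true_pupil_phase(coeffs: ZernikeCoefficients, grid: FrequencyGrid) -> np.ndarray:
    """Piston-removed reference wavefront phase in radians."""
    w = 2 * np.pi * wavefront_from_coeffs(coeffs, grid)
    _, _, support = unit_disk_coordinates(grid)
    mean = w[support].mean()
    return np.where(support, w - mean, 0.0)
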