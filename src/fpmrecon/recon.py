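"""Iterative Fourier-ptychographic reconstruction.

Four interchangeable update rules share one engine:

``ap``
    Classic alternating-projection spectrum stitching with a fixed ideal
    pupil (max-normalised PIE-style step).
``aa``
    Adaptive-step variant: per-frame intensity-offset denoising plus a
    data-derived modulation factor ``alpha`` in the spectrum step; pupil
    stays fixed and ideal.
``epry``
    Embedded pupil recovery: the ePIE-style joint update of object spectrum
    and pupil, which estimates the aberration from the data alone.
``aap``
    Adaptive aberration-corrected recovery: the ``aa`` spectrum step and a
    symmetric, ratio-weighted adaptive pupil step — both driven by the same
    modulation factor — so spectrum stitching and aberration estimation
    reinforce each other.

The adaptive factor is ``alpha = 2 max|P| - tau`` where ``tau`` is the mean,
over the dataset, of the per-frame offsets ``<I_m> - <I_t>`` between measured
and currently predicted intensities.  Per-pixel ratio maps
``W1 = |P| / max|P|`` (spectrum step) and ``W2 = |S_crop| / max|S_crop|``
(pupil step) damp the update where the multiplying function is already
strong, preventing sudden pupil jumps while leaving weakly constrained
pixels a large step ``(alpha - W)``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from skimage.transform import resize

from .forward import (LRStack, Pupil, fft2c, ifft2c, ideal_pupil,
                      _crop_slices)
from .geometry import frequency_grid

__all__ = [
    "ALGORITHMS", "ReconConfig", "IterationState", "ReconResult",
    "initialize_state", "denoise_threshold", "replace_amplitude",
    "compute_tau_alpha", "ratio_map", "convergence_error",
    "run_reconstruction",
]

ALGORITHMS = ("ap", "aa", "epry", "aap")


@dataclass(frozen=True)
class ReconConfig:
    """Knobs of the iterative engine.

    ``denoise`` defaults to the algorithm's own convention (on for the
    adaptive variants, off for ``ap`` / ``epry``); pass a bool to override.
    ``zeta1`` / ``zeta2`` regularise the divisions in the adaptive spectrum
    and pupil steps; both are dimensionless multiples of a data-derived
    reference (peak pupil power for ``zeta1``, mean sub-spectrum power for
    ``zeta2``), and the ``zeta2`` default of 10 damps the pupil step enough
    to stay stable across random hybrid aberrations.
    """

    algorithm: str = "aap"
    max_iterations: int = 15
    tolerance: float = 1e-4
    zeta1: float = 1.0
    zeta2: float = 10.0
    enforce_support: bool = True
    denoise: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.zeta1 < 0 or self.zeta2 < 0:
            raise ValueError("regularizers must be >= 0")

    @property
    def denoise_enabled(self) -> bool:
        if self.denoise is not None:
            return self.denoise
        return self.algorithm in ("aa", "aap")

    @property
    def updates_pupil(self) -> bool:
        return self.algorithm in ("epry", "aap")


@dataclass
class IterationState:
    """Mutable spectrum / pupil estimates carried across iterations."""

    spectrum: np.ndarray          # HR spectrum estimate, complex (n_hr, n_hr)
    pupil: Pupil
    scale: float                  # (n_lr / n_hr)^2 capture-field scale
    tau: float = 0.0              # mean threshold of the previous pass
    iteration: int = 0


@dataclass
class ReconResult:
    """Recovered complex field, pupil, and the convergence record."""

    amplitude: np.ndarray
    phase: np.ndarray
    field: np.ndarray
    pupil: Pupil
    error_trace: np.ndarray
    iterations: int
    final_error: float
    config: ReconConfig
    runtime_seconds: float = dc_field(default=float("nan"))


# ----------------------------------------------------------------------
# elementary steps (unit-testable in isolation)
# ----------------------------------------------------------------------
def denoise_threshold(measured: np.ndarray,
                      estimated: np.ndarray) -> tuple[np.ndarray, float]:
    """Offset-subtraction denoising of one frame.

    The threshold is the mean intensity surplus of the measurement over the
    current forward estimate; subtracting it (clamped at zero, intensities
    cannot be negative) removes a stray-light/background pedestal without
    touching image structure.
    """
    thr = float(measured.mean() - estimated.mean())
    return np.clip(measured - thr, 0.0, None), thr


def replace_amplitude(psi: np.ndarray, denoised: np.ndarray) -> np.ndarray:
    """Amplitude constraint: keep the field's phase, impose measured modulus.

    ``denoised`` is an intensity, so the imposed modulus is its square root.
    Zero-field pixels receive the measured modulus at phase zero.
    """
    mag = np.abs(psi)
    amp = np.sqrt(denoised)
    out = np.where(mag > 0, psi / np.where(mag > 0, mag, 1.0), 1.0)
    return amp * out


def compute_tau_alpha(thresholds: np.ndarray | list,
                      pupil: Pupil) -> tuple[float, float]:
    """Dataset-mean threshold tau and adaptive factor ``alpha = 2 max|P| - tau``."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size < 1:
        raise ValueError("need at least one per-frame threshold")
    tau = float(thresholds.mean())
    return tau, 2.0 * float(np.abs(pupil.values).max()) - tau


def ratio_map(magnitude: np.ndarray) -> np.ndarray:
    """Elementwise |field| / max|field| in [0, 1]; rejects an all-zero field."""
    m = np.abs(magnitude)
    peak = m.max()
    if peak == 0:
        raise ValueError("ratio map of an all-zero field is undefined")
    return m / peak


def convergence_error(stack: LRStack, state: IterationState) -> float:
    """Normalised amplitude-domain data-fidelity error of the current state.

    ``sum_m mean_r (sqrt(I_m) - |psi_m|)^2 / sum_m mean_r I_m`` — zero iff the
    forward model reproduces every measured frame, and invariant under a
    common rescaling of measurements and object.
    """
    num = 0.0
    den = 0.0
    shifts = stack.illumination.pixel_shifts
    n_hr = state.spectrum.shape[0]
    n_lr = state.pupil.values.shape[0]
    for m in range(stack.n_frames):
        rs, cs = _crop_slices(n_hr, n_lr, tuple(shifts[m]))
        psi = state.scale * ifft2c(state.spectrum[rs, cs] * state.pupil.values)
        num += float(np.mean((np.sqrt(stack.frames[m]) - np.abs(psi)) ** 2))
        den += float(np.mean(stack.frames[m]))
    return num / den if den > 0 else 0.0


# ----------------------------------------------------------------------
# initialisation
# ----------------------------------------------------------------------
def initialize_state(stack: LRStack, config: ReconConfig) -> IterationState:
    """Initial HR spectrum from the central (on-axis) capture; ideal pupil.

    The square root of the central-LED intensity is bilinearly upsampled to
    the HR grid and Fourier transformed; the pupil starts as the plain NA
    cutoff disk regardless of any aberration present in the data.
    """
    geom = stack.geometry
    grid = frequency_grid(geom)
    shifts = stack.illumination.pixel_shifts
    ci = stack.illumination.central_index
    if tuple(shifts[ci]) != (0, 0):
        raise ValueError("stack lacks an on-axis central frame")
    amp = np.sqrt(stack.central_frame())
    up = resize(amp, (geom.hr_size, geom.hr_size), order=1,
                anti_aliasing=False, preserve_range=True)
    return IterationState(
        spectrum=fft2c(up.astype(complex)),
        pupil=ideal_pupil(grid),
        scale=(grid.n_lr / grid.n_hr) ** 2,
    )


# ----------------------------------------------------------------------
# per-frame updates
# ----------------------------------------------------------------------
def _update_ap(region: np.ndarray, pupil_vals: np.ndarray,
               delta: np.ndarray) -> np.ndarray:
    pmax2 = float(np.abs(pupil_vals).max()) ** 2
    return region + np.conj(pupil_vals) / pmax2 * delta


def _update_adaptive_spectrum(region: np.ndarray, pupil_vals: np.ndarray,
                              delta: np.ndarray, alpha: float,
                              zeta1: float) -> np.ndarray:
    # zeta1 is specified relative to the squared pupil peak so the step is
    # invariant to an overall rescaling of the transfer function
    mag2 = np.abs(pupil_vals) ** 2
    w1 = ratio_map(pupil_vals)
    return region + (alpha - w1) * np.conj(pupil_vals) / (
        mag2 + zeta1 * mag2.max()) * delta


def _update_adaptive_pupil(pupil_vals: np.ndarray, region: np.ndarray,
                           delta: np.ndarray, beta: float,
                           zeta2: float) -> np.ndarray:
    # zeta2 is relative to the mean squared sub-spectrum magnitude: spectra
    # carry the arbitrary scale of the measured intensities, so only a
    # data-relative regularizer keeps the dimensionless pupil update
    # scale-invariant; referencing the mean (not the DC-dominated peak)
    # leaves pixels of typical spectral power a near-full corrective step
    mag2 = np.abs(region) ** 2
    w2 = ratio_map(region)
    return pupil_vals + (beta - w2) * np.conj(region) / (
        mag2 + zeta2 * mag2.mean()) * delta


def _clamp_transmission(pupil_vals: np.ndarray) -> np.ndarray:
    # a passive pupil cannot amplify: cap |P| at 1 (phase untouched)
    mag = np.abs(pupil_vals)
    over = mag > 1.0
    return np.where(over, pupil_vals / np.where(over, mag, 1.0), pupil_vals)


def _update_epry_pupil(pupil_vals: np.ndarray, region: np.ndarray,
                       delta: np.ndarray) -> np.ndarray:
    # classic PIE-style weighted regularized step: the per-pixel gain scales
    # as |S|/max|S| (first power).  A plain conj(S)/max|S|^2 quotient has
    # gain (|S|/max|S|)^2, which on natural scenes -- whose spectra carry a
    # dominant DC/low-frequency peak -- is ~1e-4 at typical pupil pixels and
    # cannot recover the pupil in any realistic number of passes
    mag = np.abs(region)
    smax = float(mag.max())
    mag2 = mag ** 2
    # the guard only needs to prevent division blow-up at near-empty
    # spectrum pixels; anything larger suppresses the |S|/max|S| gain at
    # typical (dim) pixels and stalls pupil recovery
    return pupil_vals + (mag / smax) * np.conj(region) / (
        mag2 + 1e-6 * smax ** 2) * delta


# ----------------------------------------------------------------------
# engine
# ----------------------------------------------------------------------
def run_reconstruction(stack: LRStack, config: ReconConfig,
                       iteration_callback: Callable[[IterationState], None] | None = None
                       ) -> ReconResult:
    """Run the configured algorithm to convergence.

    Each full pass visits the frames centre-outward; per frame the current
    sub-spectrum is propagated to the camera, optionally denoised against,
    amplitude-constrained, and the difference spectrum is fed back through
    the algorithm's spectrum (and, for ``epry`` / ``aap``, pupil) step.  The
    run stops after ``max_iterations`` passes or when the relative change of
    the data-fidelity error drops below ``tolerance``.

    The adaptive factor of a pass uses the mean threshold collected during
    the previous pass (zero on the first pass, when no prediction exists yet).
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    t0 = time.perf_counter()
    state = initialize_state(stack, config)
    n_hr = state.spectrum.shape[0]
    n_lr = state.pupil.values.shape[0]
    shifts = stack.illumination.pixel_shifts
    order = stack.illumination.order
    support = state.pupil.support

    errors: list[float] = []
    prev_err = None
    for it in range(config.max_iterations):
        state.iteration = it
        if config.algorithm in ("aa", "aap"):
            _, alpha = compute_tau_alpha([state.tau], state.pupil)
        else:
            alpha = None
        thresholds: list[float] = []
        err_num = 0.0
        err_den = 0.0
        for m in order:
            rs, cs = _crop_slices(n_hr, n_lr, tuple(shifts[m]))
            region = state.spectrum[rs, cs]
            phi = region * state.pupil.values
            psi = state.scale * ifft2c(phi)
            est_intensity = np.abs(psi) ** 2
            measured = stack.frames[m]

            err_num += float(np.mean((np.sqrt(measured) - np.abs(psi)) ** 2))
            err_den += float(np.mean(measured))

            if config.denoise_enabled:
                denoised, thr = denoise_threshold(measured, est_intensity)
                thresholds.append(thr)
            else:
                denoised = measured
            phi_new = fft2c(replace_amplitude(psi, denoised)) / state.scale
            delta = phi_new - phi

            region_old = region.copy()
            if config.algorithm == "ap":
                state.spectrum[rs, cs] = _update_ap(region, state.pupil.values, delta)
            elif config.algorithm == "aa":
                state.spectrum[rs, cs] = _update_adaptive_spectrum(
                    region, state.pupil.values, delta, alpha, config.zeta1)
            elif config.algorithm == "epry":
                state.spectrum[rs, cs] = _update_ap(region, state.pupil.values, delta)
                new_p = _update_epry_pupil(state.pupil.values, region_old, delta)
                state.pupil.values = new_p * support if config.enforce_support else new_p
            else:  # aap
                # spectrum first, then the pupil against the freshly updated
                # sub-spectrum (sequential sweep): the pupil step then sees
                # only the residual the spectrum step could not absorb,
                # which keeps the near-full adaptive steps stable
                state.spectrum[rs, cs] = _update_adaptive_spectrum(
                    region, state.pupil.values, delta, alpha, config.zeta1)
                new_p = _clamp_transmission(_update_adaptive_pupil(
                    state.pupil.values, state.spectrum[rs, cs], delta, alpha,
                    config.zeta2))
                state.pupil.values = new_p * support if config.enforce_support else new_p

        if not np.all(np.isfinite(state.spectrum)):
            raise FloatingPointError(
                f"non-finite spectrum at iteration {it + 1}; the run diverged")
        if thresholds:
            state.tau = float(np.mean(thresholds))
        err = err_num / err_den if err_den > 0 else 0.0
        errors.append(err)
        if iteration_callback is not None:
            iteration_callback(state)
        if prev_err is not None and prev_err > 0:
            if abs(prev_err - err) / prev_err < config.tolerance:
                break
        prev_err = err

    field_ = ifft2c(state.spectrum)
    return ReconResult(
        amplitude=np.abs(field_),
        phase=np.angle(field_),
        field=field_,
        pupil=state.pupil,
        error_trace=np.asarray(errors),
        iterations=len(errors),
        final_error=errors[-1],
        config=config,
        runtime_seconds=time.perf_counter() - t0,
    )
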