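"""Coherent forward model: pupils, low-resolution capture, dataset synthesis.

A thin sample is described by its complex transmission ``o(r)``.  Under the
m-th LED the objective passes the sub-spectrum of ``O(u) = F{o}`` centred at
the illumination wave vector ``U_m``, filtered by the pupil ``P(u)``, and the
camera records the intensity

    ``I_m(r) = | F^{-1}{ O(u - U_m) P(u) } |^2``.

Spectra are kept centred (DC at pixel ``n // 2``) throughout; the capture
field carries a ``(n_lr / n_hr)^2`` scale so that a uniform object of
amplitude ``A`` produces a frame of intensity ``A^2`` — intensities stay on
the object scale regardless of grid sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.fft import fft2, ifft2, fftshift, ifftshift
from scipy import ndimage

from .geometry import (SystemGeometry, FrequencyGrid, IlluminationSet,
                       frequency_grid, led_wavevectors)
from .zernike import ZernikeCoefficients, wavefront_from_coeffs, unit_disk_coordinates

__all__ = [
    "ObjectField", "Pupil", "LRStack", "SceneSpec",
    "fft2c", "ifft2c",
    "ideal_pupil", "aberrated_pupil", "forward_capture",
    "simulate_dataset", "make_synthetic_scene",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centred 2-D Fourier transform (DC at ``n // 2``)."""
    return fftshift(fft2(ifftshift(x)))


def ifft2c(x: np.ndarray) -> np.ndarray:
    return fftshift(ifft2(ifftshift(x)))


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class ObjectField:
    """Complex sample transmission as an amplitude / phase pair."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if np.any(self.amplitude < 0) or not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite and non-negative")

    @property
    def complex(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)

    @classmethod
    def from_complex(cls, field_: np.ndarray) -> "ObjectField":
        return cls(np.abs(field_), np.angle(field_))


@dataclass
class Pupil:
    """Coherent transfer function on the capture-sized frequency grid."""

    values: np.ndarray   # complex
    support: np.ndarray  # bool, the NA cutoff disk

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class LRStack:
    """Ordered set of low-resolution intensity captures plus provenance."""

    frames: np.ndarray                      # (M, n_lr, n_lr), >= 0
    geometry: SystemGeometry
    illumination: IlluminationSet
    truth_object: Optional[ObjectField] = None
    truth_coeffs: Optional[ZernikeCoefficients] = None
    seed: Optional[int] = field(default=None)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] != self.geometry.n_leds:
            raise ValueError(
                f"expected {self.geometry.n_leds} frames, got shape {f.shape}")
        if f.shape[1] != self.geometry.lr_size or f.shape[2] != self.geometry.lr_size:
            raise ValueError("frame size does not match geometry lr_size")
        if np.any(f < 0):
            raise ValueError("intensities must be non-negative")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def central_frame(self) -> np.ndarray:
        return self.frames[self.illumination.central_index]


# ----------------------------------------------------------------------
# pupils
# ----------------------------------------------------------------------
def ideal_pupil(grid: FrequencyGrid) -> Pupil:
    """Aberration-free binary pupil: 1 inside the NA cutoff disk, 0 outside."""
    _, _, support = unit_disk_coordinates(grid)
    return Pupil(values=support.astype(complex), support=support)


def aberrated_pupil(grid: FrequencyGrid, coeffs: ZernikeCoefficients) -> Pupil:
    """Unit-amplitude pupil with phase ``2 pi sum_j a_j Z_j`` on its support."""
    p = ideal_pupil(grid)
    w = wavefront_from_coeffs(coeffs, grid)
    return Pupil(values=p.support * np.exp(2j * np.pi * w), support=p.support)


# ----------------------------------------------------------------------
# capture
# ----------------------------------------------------------------------
def _crop_slices(n_hr: int, n_lr: int, shift: tuple[int, int]) -> tuple[slice, slice]:
    """Half-open lr-sized window centred at (grid centre + shift)."""
    cr = n_hr // 2 + int(shift[0])
    cc = n_hr // 2 + int(shift[1])
    h = n_lr // 2
    r0, c0 = cr - h, cc - h
    if r0 < 0 or c0 < 0 or r0 + n_lr > n_hr or c0 + n_lr > n_hr:
        raise ValueError(f"sub-aperture crop at shift {shift} leaves the grid")
    return slice(r0, r0 + n_lr), slice(c0, c0 + n_lr)


def capture_field(spectrum_hr: np.ndarray, pupil: Pupil,
                  shift: tuple[int, int]) -> np.ndarray:
    """Complex low-resolution field behind the objective for one LED."""
    n_hr = spectrum_hr.shape[0]
    n_lr = pupil.values.shape[0]
    rs, cs = _crop_slices(n_hr, n_lr, shift)
    scale = (n_lr / n_hr) ** 2
    return scale * ifft2c(spectrum_hr[rs, cs] * pupil.values)


def forward_capture(obj: ObjectField, pupil: Pupil,
                    shift: tuple[int, int]) -> np.ndarray:
    """Intensity frame for one LED (squared magnitude of the capture field)."""
    spectrum = fft2c(obj.complex)
    psi = capture_field(spectrum, pupil, shift)
    return np.abs(psi) ** 2


# ----------------------------------------------------------------------
# scenes
# ----------------------------------------------------------------------
_PATTERNS = ("blobs", "speckle", "strokes")


def _rescale01(im: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    rng_ = im.max() - im.min()
    if rng_ == 0:
        return np.full_like(im, (lo + hi) / 2)
    return lo + (hi - lo) * (im - im.min()) / rng_


def _texture(rng: np.random.Generator, size: int, pattern: str) -> np.ndarray:
    # smoothing scales keep essentially all scene energy inside the
    # synthetic-NA passband of the reference system (cutoff ~0.11 cycles/px,
    # i.e. features coarser than ~3 px) while leaving a substantial share
    # beyond the objective passband, so recovery is a genuine
    # super-resolution problem yet the scene remains representable by a
    # converged reconstruction
    if pattern == "blobs":
        base = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 48)
        fine = ndimage.gaussian_filter(rng.standard_normal((size, size)), 3.0)
        im = base + 0.45 * fine
    elif pattern == "speckle":
        # band-limited random field: white noise low-passed at two scales
        im = (ndimage.gaussian_filter(rng.standard_normal((size, size)), 3.0)
              + 0.5 * ndimage.gaussian_filter(rng.standard_normal((size, size)), 6.0))
    elif pattern == "strokes":
        im = np.zeros((size, size))
        for _ in range(max(12, size // 16)):
            r0, c0 = rng.integers(0, size, 2)
            length = int(rng.integers(size // 16, size // 3))
            ang = rng.uniform(0, np.pi)
            rr = np.clip(np.rint(r0 + np.arange(length) * np.sin(ang)).astype(int), 0, size - 1)
            cc = np.clip(np.rint(c0 + np.arange(length) * np.cos(ang)).astype(int), 0, size - 1)
            im[rr, cc] += rng.uniform(0.5, 1.0)
        im = ndimage.gaussian_filter(im, 2.5)
        im += 0.2 * ndimage.gaussian_filter(rng.standard_normal((size, size)), 3.0)
    else:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {_PATTERNS}")
    return _rescale01(im)


def make_synthetic_scene(pattern: str, size: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Reproducible procedural (amplitude, phase) scene pair in [0, 1].

    The two images are drawn from independent substreams of ``seed`` so
    amplitude and phase carry uncorrelated structure, as in the two-image
    ground truths used for simulation studies.  Feature scales are chosen so
    most spectral energy lies inside a ~0.5 synthetic NA while a measurable
    share falls outside the 0.1 NA objective passband (otherwise
    super-resolution recovery would be trivial).
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {_PATTERNS}")
    ss = np.random.SeedSequence(seed)
    rng_a, rng_p = (np.random.default_rng(s) for s in ss.spawn(2))
    amp = _rescale01(_texture(rng_a, size, pattern), 0.1, 1.0)
    phase = _texture(rng_p, size, pattern)
    return amp, phase


@dataclass
class SceneSpec:
    """Recipe for the ground-truth complex object of a simulation.

    ``amplitude`` / ``phase`` are either procedural pattern ids
    (one of ``blobs``, ``speckle``, ``strokes``), image file paths, or
    ready-made arrays in [0, 1].  The phase image is scaled to
    ``phase_scale_rad`` radians peak-to-peak.
    """

    amplitude: object = "blobs"
    phase: object = "speckle"
    size: int = 512
    phase_scale_rad: float = 1.0
    seed: int = 0

    def _resolve_one(self, source, rng_tag: int) -> np.ndarray:
        if isinstance(source, np.ndarray):
            im = np.asarray(source, dtype=float)
        elif isinstance(source, str) and source in _PATTERNS:
            amp, ph = make_synthetic_scene(source, self.size, self.seed + rng_tag)
            im = amp if rng_tag == 0 else ph
        else:  # file path
            import imageio.v3 as iio
            im = np.asarray(iio.imread(source), dtype=float)
            if im.ndim == 3:
                im = im.mean(axis=2)
            im = _rescale01(im)
        if im.shape != (self.size, self.size):
            raise ValueError(
                f"scene image shape {im.shape} != ({self.size}, {self.size})")
        if im.min() < 0 or im.max() > 1:
            raise ValueError("scene images must lie in [0, 1]")
        return im

    def resolve(self) -> ObjectField:
        amp = self._resolve_one(self.amplitude, 0)
        ph = self._resolve_one(self.phase, 1)
        return ObjectField(amplitude=amp, phase=ph * self.phase_scale_rad)


# ----------------------------------------------------------------------
# dataset synthesis
# ----------------------------------------------------------------------
def simulate_dataset(scene: SceneSpec | ObjectField, geometry: SystemGeometry,
                     coeffs: ZernikeCoefficients | None = None) -> LRStack:
    """Generate the full low-resolution capture stack for one experiment.

    Every LED of the array is simulated; frames are stored in row-major LED
    order (the update ordering lives in ``illumination.order``).  Ground
    truth is retained on the stack for later evaluation.  No sensor noise is
    added: the only perturbation of an otherwise ideal system is the pupil
    aberration given by ``coeffs``.
    """
    obj = scene.resolve() if isinstance(scene, SceneSpec) else scene
    if obj.amplitude.shape != (geometry.hr_size, geometry.hr_size):
        raise ValueError(
            f"scene is {obj.amplitude.shape}, geometry expects "
            f"({geometry.hr_size}, {geometry.hr_size})")
    grid = frequency_grid(geometry)
    illum = led_wavevectors(geometry)
    if coeffs is None:
        coeffs = ZernikeCoefficients.zeros()
    pupil = aberrated_pupil(grid, coeffs)
    spectrum = fft2c(obj.complex)
    frames = np.empty((illum.n_leds, grid.n_lr, grid.n_lr))
    for m in range(illum.n_leds):
        psi = capture_field(spectrum, pupil, tuple(illum.pixel_shifts[m]))
        frames[m] = np.abs(psi) ** 2
    seed = coeffs.rng_seed
    return LRStack(frames=frames, geometry=geometry, illumination=illum,
                   truth_object=obj, truth_coeffs=coeffs, seed=seed)
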