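"""Optical system geometry for an LED-array Fourier ptychographic microscope.

The geometry couples three pieces of the imaging model:

* the LED array, which sets the illumination wave vector ``U_m`` of every
  low-resolution capture,
* the objective, whose numerical aperture defines the coherent transfer
  function (pupil) cutoff, and
* the camera / magnification pair, which fixes the object-side sampling and
  therefore the discrete frequency grid on which spectra and pupils live.

All lengths are carried with explicit units in the field names (mm, nm, um);
spatial frequencies are in cycles per micrometre.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SystemGeometry",
    "FrequencyGrid",
    "IlluminationSet",
    "frequency_grid",
    "led_wavevectors",
    "synthetic_na",
    "overlap_rate",
]


@dataclass(frozen=True)
class SystemGeometry:
    """Physical description of the FPM platform.

    Defaults describe the reference configuration used throughout this
    package: a 15x15 green LED array (4 mm pitch) 90.88 mm below the sample,
    531 nm illumination, a 4x / 0.1 NA objective and a 1.845 um camera pixel,
    reconstructing a 512x512 high-resolution field from 128x128 captures.
    """

    led_rows: int = 15
    led_cols: int = 15
    led_pitch_mm: float = 4.0
    led_distance_mm: float = 90.88
    wavelength_nm: float = 531.0
    objective_na: float = 0.1
    magnification: float = 4.0
    camera_pixel_um: float = 1.845
    hr_size: int = 512
    upsample_factor: int = 4

    def __post_init__(self) -> None:
        for name in ("led_pitch_mm", "led_distance_mm", "wavelength_nm",
                     "magnification", "camera_pixel_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.led_rows < 1 or self.led_cols < 1:
            raise ValueError("LED array counts must be >= 1")
        if self.led_rows % 2 == 0 or self.led_cols % 2 == 0:
            raise ValueError("LED array must be odd-sized so a central, "
                             "on-axis LED exists")
        if not 0 < self.objective_na < 1:
            raise ValueError("objective_na must lie in (0, 1)")
        if self.upsample_factor < 1 or self.hr_size % self.upsample_factor:
            raise ValueError("upsample_factor must be >= 1 and divide hr_size")

    # ------------------------------------------------------------------
    # derived sampling quantities
    # ------------------------------------------------------------------
    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def lr_size(self) -> int:
        return self.hr_size // self.upsample_factor

    @property
    def lr_pixel_um(self) -> float:
        """Object-side pixel of the raw captures (camera pixel / magnification)."""
        return self.camera_pixel_um / self.magnification

    @property
    def hr_pixel_um(self) -> float:
        return self.lr_pixel_um / self.upsample_factor

    @property
    def n_leds(self) -> int:
        return self.led_rows * self.led_cols

    # ------------------------------------------------------------------
    # (de)serialisation
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SystemGeometry":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class FrequencyGrid:
    """Discretisation of the Fourier plane shared by spectra and pupils.

    The frequency step is identical on the high-resolution grid
    (``n_hr`` pixels of ``hr_pixel_um``) and the low-resolution capture grid
    (``n_lr`` pixels of ``lr_pixel_um``), so a sub-aperture crop of the HR
    spectrum aligns pixel-for-pixel with the pupil.
    """

    n_hr: int
    n_lr: int
    du_per_um: float          # frequency step, cycles/um per pixel
    pupil_radius_px: float    # objective cutoff (NA/lambda)/du

    def __post_init__(self) -> None:
        if self.du_per_um <= 0:
            raise ValueError("frequency step must be > 0")
        if self.pupil_radius_px >= self.n_lr / 2:
            raise ValueError("pupil does not fit inside the capture grid; "
                             "increase upsampling or camera pixel count")


def frequency_grid(geometry: SystemGeometry) -> FrequencyGrid:
    du = 1.0 / (geometry.hr_size * geometry.hr_pixel_um)
    cutoff = geometry.objective_na / geometry.wavelength_um
    return FrequencyGrid(
        n_hr=geometry.hr_size,
        n_lr=geometry.lr_size,
        du_per_um=du,
        pupil_radius_px=cutoff / du,
    )


@dataclass(frozen=True)
class IlluminationSet:
    """Per-LED illumination wave vectors and their discrete grid positions.

    Arrays are indexed by a flat LED index ``m`` (row-major over the array);
    ``order`` is the centre-outward permutation in which the reconstruction
    visits the frames.
    """

    offsets_mm: np.ndarray     # (M, 2) LED offsets (x, y) from the axis
    wavevectors: np.ndarray    # (M, 2) U_m = (ux, uy), cycles/um
    pixel_shifts: np.ndarray   # (M, 2) integer (row, col) shift on the HR grid
    order: np.ndarray          # (M,) permutation of range(M)
    central_index: int = field(default=0)

    @property
    def n_leds(self) -> int:
        return self.wavevectors.shape[0]

    def illumination_na(self, geometry: SystemGeometry) -> np.ndarray:
        """|sin theta| of every LED (= lambda |U_m|)."""
        return geometry.wavelength_um * np.hypot(*self.wavevectors.T)


def led_wavevectors(geometry: SystemGeometry) -> IlluminationSet:
    """Illumination wave vectors, pixel shifts and update order for every LED.

    The incidence angle of each LED is taken from its exact 3-D position:
    for an LED offset ``(ox, oy)`` at distance ``z`` below the sample,
    ``sin(theta_x) = ox / sqrt(ox^2 + oy^2 + z^2)`` (and likewise for y), so
    oblique corner LEDs are handled without a small-angle approximation.
    ``U_m = (sin(theta_x), sin(theta_y)) / lambda``.

    Wave vectors are rounded to the nearest pixel of the HR frequency grid;
    a geometry whose outermost sub-aperture would leave the grid is rejected.
    """
    grid = frequency_grid(geometry)
    half_r = geometry.led_rows // 2
    half_c = geometry.led_cols // 2
    rows, cols = np.mgrid[-half_r:half_r + 1, -half_c:half_c + 1]
    ox = cols.ravel() * geometry.led_pitch_mm      # x offset, mm
    oy = rows.ravel() * geometry.led_pitch_mm      # y offset, mm
    z = geometry.led_distance_mm
    norm = np.sqrt(ox ** 2 + oy ** 2 + z ** 2)
    sin_tx = ox / norm
    sin_ty = oy / norm
    wavevectors = np.stack([sin_tx, sin_ty], axis=1) / geometry.wavelength_um

    # (row, col) pixel shift on the frequency grid: row tracks uy, col ux
    shifts = np.stack(
        [np.rint(sin_ty / geometry.wavelength_um / grid.du_per_um),
         np.rint(sin_tx / geometry.wavelength_um / grid.du_per_um)],
        axis=1,
    ).astype(int)

    max_shift = np.abs(shifts).max() if shifts.size else 0
    if max_shift + grid.n_lr // 2 > grid.n_hr // 2:
        raise ValueError(
            "outermost sub-aperture falls off the frequency grid "
            f"(shift {max_shift} px + crop half-width {grid.n_lr // 2} px "
            f"exceeds {grid.n_hr // 2} px); enlarge hr_size or reduce the "
            "illumination angle")

    radius = np.hypot(ox, oy)
    ring = np.maximum(np.abs(rows.ravel()), np.abs(cols.ravel()))
    angle = np.arctan2(oy, ox)
    # centre-outward spiral: concentric square rings, swept by angle
    order = np.lexsort((angle, radius, ring))
    central = int(np.flatnonzero((ox == 0) & (oy == 0))[0])

    return IlluminationSet(
        offsets_mm=np.stack([ox, oy], axis=1),
        wavevectors=wavevectors,
        pixel_shifts=shifts,
        order=order,
        central_index=central,
    )


def synthetic_na(geometry: SystemGeometry) -> float:
    """Synthetic numerical aperture: objective NA + largest illumination NA."""
    illum = led_wavevectors(geometry)
    return geometry.objective_na + float(illum.illumination_na(geometry).max())


def overlap_rate(geometry: SystemGeometry) -> float:
    """Fractional Fourier-domain overlap of two adjacent sub-apertures.

    Counted on the discrete frequency grid: pixels inside both circular pupil
    supports (radius = objective cutoff, centres one LED step apart) divided
    by the pixels inside a single support.  Sufficient overlap (commonly
    >60%) is what makes iterative spectrum stitching converge; a
    non-overlapping layout is reported as 0 with a warning.
    """
    grid = frequency_grid(geometry)
    z = geometry.led_distance_mm
    p = geometry.led_pitch_mm
    sin_step = p / math.hypot(p, z)
    shift_px = sin_step / geometry.wavelength_um / grid.du_per_um
    r = grid.pupil_radius_px

    if shift_px >= 2 * r:
        warnings.warn(
            "adjacent sub-apertures do not overlap (centre distance "
            f"{shift_px:.1f} px >= diameter {2 * r:.1f} px); Fourier "
            "ptychographic stitching cannot converge for this geometry",
            stacklevel=2)
        return 0.0

    half = int(math.ceil(r + shift_px)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    in_a = (xx ** 2 + yy ** 2) <= r ** 2
    in_b = ((xx - shift_px) ** 2 + yy ** 2) <= r ** 2
    return float(np.sum(in_a & in_b) / np.sum(in_a))
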