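"""Zernike wavefront basis, aberration sampling and modal decomposition.

The basis is the unnormalised single-index convention commonly used for
microscope aberration budgets: mode 1 is piston, 2/3 tilt, 4 defocus,
5/6 primary astigmatism, 7/8 primary coma, 9/10 primary trefoil,
11 primary spherical, 12/13 secondary astigmatism, 14/15 primary tetrafoil.
Polynomials carry no Noll-style sqrt(n+1) factors, so a coefficient ``a_j``
is directly the peak contribution of that mode in waves and the pupil phase
is ``2 * pi * sum_j a_j Z_j(rho, theta)`` radians.

Modes 16-25 extend the same scheme through radial orders five and six
(secondary coma/trefoil, pentafoil, secondary spherical, tertiary
astigmatism, secondary tetrafoil); they matter only for decomposing
recovered pupils, not for synthesising the hybrid aberrations studied here.

Angular convention: ``theta`` is measured from the +x (column) frequency
axis, counter-clockwise towards +y (row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import FrequencyGrid

__all__ = [
    "JMAX",
    "ZernikeCoefficients",
    "zernike_eval",
    "wavefront_from_coeffs",
    "sample_random_coeffs",
    "zernike_decompose",
    "unit_disk_coordinates",
]

# mode -> (polynomial, human name); rho and theta are broadcastable arrays
_MODES: dict[int, tuple[Callable[[np.ndarray, np.ndarray], np.ndarray], str]] = {
    1: (lambda r, t: np.ones_like(r), "piston"),
    2: (lambda r, t: r * np.cos(t), "tilt x"),
    3: (lambda r, t: r * np.sin(t), "tilt y"),
    4: (lambda r, t: 2 * r**2 - 1, "defocus"),
    5: (lambda r, t: r**2 * np.sin(2 * t), "primary astigmatism x"),
    6: (lambda r, t: r**2 * np.cos(2 * t), "primary astigmatism y"),
    7: (lambda r, t: (3 * r**2 - 2) * r * np.sin(t), "primary coma x"),
    8: (lambda r, t: (3 * r**2 - 2) * r * np.cos(t), "primary coma y"),
    9: (lambda r, t: r**3 * np.cos(3 * t), "primary trefoil x"),
    10: (lambda r, t: r**3 * np.sin(3 * t), "primary trefoil y"),
    11: (lambda r, t: 6 * r**4 - 6 * r**2 + 1, "primary spherical"),
    12: (lambda r, t: (4 * r**2 - 3) * r**2 * np.cos(2 * t), "secondary astigmatism x"),
    13: (lambda r, t: (4 * r**2 - 3) * r**2 * np.sin(2 * t), "secondary astigmatism y"),
    14: (lambda r, t: r**4 * np.cos(4 * t), "primary tetrafoil x"),
    15: (lambda r, t: r**4 * np.sin(4 * t), "primary tetrafoil y"),
    # radial order 5 (sin/cos ordering mirrors the order-3 row above)
    16: (lambda r, t: (10 * r**4 - 12 * r**2 + 3) * r * np.sin(t), "secondary coma x"),
    17: (lambda r, t: (10 * r**4 - 12 * r**2 + 3) * r * np.cos(t), "secondary coma y"),
    18: (lambda r, t: (5 * r**2 - 4) * r**3 * np.cos(3 * t), "secondary trefoil x"),
    19: (lambda r, t: (5 * r**2 - 4) * r**3 * np.sin(3 * t), "secondary trefoil y"),
    20: (lambda r, t: r**5 * np.cos(5 * t), "primary pentafoil x"),
    21: (lambda r, t: r**5 * np.sin(5 * t), "primary pentafoil y"),
    # radial order 6 (cos/sin ordering mirrors the order-4 row above)
    22: (lambda r, t: 20 * r**6 - 30 * r**4 + 12 * r**2 - 1, "secondary spherical"),
    23: (lambda r, t: (15 * r**4 - 20 * r**2 + 6) * r**2 * np.cos(2 * t), "tertiary astigmatism x"),
    24: (lambda r, t: (15 * r**4 - 20 * r**2 + 6) * r**2 * np.sin(2 * t), "tertiary astigmatism y"),
    25: (lambda r, t: (6 * r**2 - 5) * r**4 * np.cos(4 * t), "secondary tetrafoil x"),
}

JMAX = max(_MODES)


def mode_name(j: int) -> str:
    return _MODES[j][1]


def zernike_eval(j: int, rho, theta) -> np.ndarray | float:
    """Evaluate mode ``Z_j`` at polar coordinates on the unit disk.

    ``rho`` must lie in [0, 1]; scalar inputs return a scalar.
    """
    if not 1 <= j <= JMAX:
        raise ValueError(f"mode index must be in 1..{JMAX}, got {j}")
    rho, theta = np.broadcast_arrays(np.asarray(rho, dtype=float),
                                     np.asarray(theta, dtype=float))
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    out = np.asarray(_MODES[j][0](rho, theta))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ZernikeCoefficients:
    """Modal aberration description; ``values[k]`` is ``a_{k+1}`` in waves."""

    values: np.ndarray
    rng_seed: int | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size > JMAX:
            raise ValueError(f"need a 1-d vector of at most {JMAX} coefficients")
        if not np.all(np.isfinite(v)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "values", v)

    @classmethod
    def zeros(cls, jmax: int = 15) -> "ZernikeCoefficients":
        return cls(np.zeros(jmax))

    def __len__(self) -> int:
        return self.values.size

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps([{"j": j + 1, "a_j": float(a)}
                           for j, a in enumerate(self.values)])

    @classmethod
    def from_json(cls, text: str) -> "ZernikeCoefficients":
        entries = json.loads(text)
        jmax = max(e["j"] for e in entries)
        v = np.zeros(jmax)
        for e in entries:
            v[e["j"] - 1] = e["a_j"]
        return cls(v)


def unit_disk_coordinates(grid: "FrequencyGrid") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rho, theta, support) on the capture-sized frequency grid.

    ``rho`` is normalised so the objective NA cutoff sits at rho = 1; theta
    runs counter-clockwise from the +x frequency axis.
    """
    n = grid.n_lr
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    x = (xx - c).astype(float)
    y = (yy - c).astype(float)
    rho = np.hypot(x, y) / grid.pupil_radius_px
    theta = np.arctan2(y, x)
    return rho, theta, rho <= 1.0


def wavefront_from_coeffs(coeffs: ZernikeCoefficients, grid: "FrequencyGrid") -> np.ndarray:
    """Aberration wavefront ``sum_j a_j Z_j`` in waves, zero outside the pupil."""
    rho, theta, support = unit_disk_coordinates(grid)
    w = np.zeros_like(rho)
    r = np.where(support, rho, 0.0)
    for k, a in enumerate(coeffs.values):
        if a != 0.0:
            w += a * _MODES[k + 1][0](r, theta)
    w[~support] = 0.0
    return w


def sample_random_coeffs(seed: int, jmax: int = 15,
                         bound: float = 0.2) -> ZernikeCoefficients:
    """Draw a hybrid aberration: ``a_j ~ U(-bound, +bound)`` independently.

    The default +/-0.2 waves over the first fifteen modes reproduces the
    severity of the mixed tilt/defocus/astigmatism/coma/trefoil/spherical/
    tetrafoil aberrations a real low-NA objective plus off-axis LED
    illumination is expected to show.
    """
    if bound < 0:
        raise ValueError("bound must be >= 0")
    rng = np.random.default_rng(seed)
    return ZernikeCoefficients(rng.uniform(-bound, bound, size=jmax),
                               rng_seed=seed)


def zernike_decompose(phase: np.ndarray, grid: "FrequencyGrid",
                      jmax: int = 25, input_units: str = "radians") -> np.ndarray:
    """Least-squares modal amplitudes (waves) of a pupil phase map.

    The phase is projected onto modes ``1..jmax`` over the discrete pupil
    disk by ordinary least squares, which stays well conditioned even though
    the sampled polynomials are not exactly orthogonal on a pixel grid.
    """
    if jmax > JMAX:
        raise ValueError(f"jmax must be <= {JMAX}")
    rho, theta, support = unit_disk_coordinates(grid)
    npix = int(support.sum())
    if npix < 2 * jmax:
        raise ValueError(
            f"pupil support of {npix} pixels is too small to fit {jmax} modes")
    if input_units == "radians":
        target = phase[support] / (2 * np.pi)
    elif input_units == "waves":
        target = phase[support]
    else:
        raise ValueError("input_units must be 'radians' or 'waves'")
    design = np.column_stack(
        [_MODES[j][0](rho[support], theta[support]) for j in range(1, jmax + 1)])
    sol, *_ = np.linalg.lstsq(design, target, rcond=None)
    return sol


def decomposition_to_csv(amplitudes: np.ndarray, path) -> None:
    """Write (mode index, amplitude in waves, name) rows."""
    with open(path, "w") as fh:
        fh.write("mode,amplitude_waves,aberration\n")
        for k, a in enumerate(amplitudes):
            fh.write(f"{k + 1},{a:.6g},{mode_name(k + 1)}\n")
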