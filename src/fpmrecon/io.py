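"""Persistence: capture stacks as multi-page TIFF + JSON sidecar, results as NPZ.

The sidecar records everything needed to regenerate or reconstruct the
stack — geometry, LED order, seed, and (for simulations) the ground-truth
Zernike coefficients — so a saved dataset is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .forward import LRStack, Pupil
from .geometry import SystemGeometry, led_wavevectors
from .recon import ReconResult, ReconConfig
from .zernike import ZernikeCoefficients

__all__ = ["save_stack", "load_stack", "save_result", "load_result"]


def save_stack(stack: LRStack, tif_path, json_path=None) -> None:
    """Write frames as 32-bit float multi-page TIFF plus a JSON sidecar."""
    tif_path = Path(tif_path)
    if json_path is None:
        json_path = tif_path.with_suffix(".json")
    tifffile.imwrite(tif_path, stack.frames.astype(np.float32))
    meta = {
        "geometry": stack.geometry.to_dict(),
        "order": stack.illumination.order.tolist(),
        "seed": stack.seed,
    }
    if stack.truth_coeffs is not None:
        meta["zernike_coefficients"] = json.loads(stack.truth_coeffs.to_json())
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_stack(tif_path, json_path=None) -> LRStack:
    """Read a stack written by :func:`save_stack` (ground-truth object is not
    persisted; coefficients are restored when present)."""
    tif_path = Path(tif_path)
    if json_path is None:
        json_path = tif_path.with_suffix(".json")
    frames = np.asarray(tifffile.imread(tif_path), dtype=float)
    with open(json_path) as fh:
        meta = json.load(fh)
    geometry = SystemGeometry.from_dict(meta["geometry"])
    illum = led_wavevectors(geometry)
    coeffs = None
    if "zernike_coefficients" in meta:
        coeffs = ZernikeCoefficients.from_json(
            json.dumps(meta["zernike_coefficients"]))
    return LRStack(frames=frames, geometry=geometry, illumination=illum,
                   truth_coeffs=coeffs, seed=meta.get("seed"))


def save_result(result: ReconResult, path) -> None:
    """Store named arrays plus a JSON provenance block in one NPZ container."""
    provenance = json.dumps({
        "algorithm": result.config.algorithm,
        "max_iterations": result.config.max_iterations,
        "tolerance": result.config.tolerance,
        "iterations": result.iterations,
        "final_error": result.final_error,
        "runtime_seconds": result.runtime_seconds,
    })
    np.savez_compressed(
        path,
        amplitude=result.amplitude,
        phase=result.phase,
        pupil_real=result.pupil.values.real,
        pupil_imag=result.pupil.values.imag,
        pupil_support=result.pupil.support,
        error_trace=result.error_trace,
        provenance=np.array(provenance),
    )


def load_result(path) -> ReconResult:
    with np.load(path, allow_pickle=False) as z:
        prov = json.loads(str(z["provenance"]))
        pupil = Pupil(values=z["pupil_real"] + 1j * z["pupil_imag"],
                      support=z["pupil_support"].astype(bool))
        field = z["amplitude"] * np.exp(1j * z["phase"])
        return ReconResult(
            amplitude=z["amplitude"], phase=z["phase"], field=field,
            pupil=pupil, error_trace=z["error_trace"],
            iterations=int(prov["iterations"]),
            final_error=float(prov["final_error"]),
            config=ReconConfig(algorithm=prov["algorithm"],
                               max_iterations=prov["max_iterations"],
                               tolerance=prov["tolerance"]),
            runtime_seconds=float(prov["runtime_seconds"]),
        )
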