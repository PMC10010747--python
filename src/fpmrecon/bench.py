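"""Configuration-driven simulation benchmark of the four reconstructors.

One seeded synthetic dataset (scene + hybrid aberration) is shared by every
algorithm — a paired comparison — and each reconstruction is scored against
the ground truth held on the stack: normalised amplitude / phase RMSE,
structural similarity of the recovered pupil phase against the true
wavefront, iteration count and final data-fidelity error.  Per-iteration
RMSE traces (the convergence curves) are recorded alongside.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .forward import LRStack, SceneSpec, simulate_dataset, ifft2c
from .geometry import SystemGeometry, frequency_grid
from .metrics import (MetricsReport, align_to_truth, recovered_pupil_phase,
                      rmse_image, shift_pupil_tilt, ssim_image,
                      true_pupil_phase)
from .recon import ReconConfig, ReconResult, run_reconstruction
from .zernike import sample_random_coeffs, zernike_decompose

__all__ = ["ExperimentSpec", "run_benchmark", "evaluate", "improvement_percent"]


@dataclass
class ExperimentSpec:
    """Complete recipe for one seeded simulation benchmark."""

    geometry: SystemGeometry = field(default_factory=SystemGeometry)
    scene: SceneSpec = field(default_factory=SceneSpec)
    aberration_seed: int = 0
    aberration_bound: float = 0.2
    aberration_jmax: int = 15
    algorithms: tuple[str, ...] = ("ap", "aa", "epry", "aap")
    max_iterations: int = 15
    tolerance: float = 1e-4
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ValueError("need at least one algorithm")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentSpec":
        kwargs = dict(raw)
        if "geometry" in kwargs:
            kwargs["geometry"] = SystemGeometry.from_dict(kwargs["geometry"])
        if "scene" in kwargs:
            kwargs["scene"] = SceneSpec(**kwargs["scene"])
        if "algorithms" in kwargs:
            kwargs["algorithms"] = tuple(kwargs["algorithms"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scene"] = {k: v for k, v in d["scene"].items()
                      if not isinstance(v, np.ndarray)}
        return d


def improvement_percent(reference_rmse: float, candidate_rmse: float) -> float:
    """Relative error reduction of a candidate over a reference, in percent."""
    if reference_rmse <= 0:
        raise ValueError("reference RMSE must be > 0")
    return 100.0 * (reference_rmse - candidate_rmse) / reference_rmse


def evaluate(result: ReconResult, stack: LRStack) -> MetricsReport:
    """Score one reconstruction against the ground truth on its stack.

    The recovered field is registered to the reference (removing the
    tilt/shift and global-phase gauges) before RMSE; the matching linear
    ramp is restored to the recovered pupil before comparing its unwrapped,
    piston-free phase with the true wavefront.
    """
    if stack.truth_object is None:
        raise ValueError("stack carries no ground truth to evaluate against")
    truth = stack.truth_object
    aligned, shift = align_to_truth(result.field, truth.complex)
    amp_rmse = rmse_image(np.abs(aligned), truth.amplitude, "amplitude")
    ph_rmse = rmse_image(np.angle(aligned), truth.phase, "phase")

    ssim = float("nan")
    if stack.truth_coeffs is not None and result.config.updates_pupil:
        grid = frequency_grid(stack.geometry)
        fixed = shift_pupil_tilt(result.pupil, shift, grid.n_hr)
        ssim = ssim_image(recovered_pupil_phase(fixed),
                          true_pupil_phase(stack.truth_coeffs, grid),
                          support=fixed.support)

    return MetricsReport(
        algorithm=result.config.algorithm,
        amplitude_rmse=amp_rmse,
        phase_rmse=ph_rmse,
        pupil_phase_ssim=ssim,
        iterations=result.iterations,
        final_error=result.final_error,
        runtime_seconds=result.runtime_seconds,
    )


def decompose_result_pupil(result: ReconResult, stack: LRStack,
                           jmax: int = 25) -> np.ndarray:
    """Zernike amplitudes (waves) of the gauge-fixed recovered pupil phase."""
    grid = frequency_grid(stack.geometry)
    if stack.truth_object is not None:
        _, shift = align_to_truth(result.field, stack.truth_object.complex)
        pupil = shift_pupil_tilt(result.pupil, shift, grid.n_hr)
    else:
        pupil = result.pupil
    return zernike_decompose(recovered_pupil_phase(pupil), grid, jmax=jmax)


def run_benchmark(spec: ExperimentSpec) -> dict:
    """Simulate once, reconstruct with every algorithm, score everything.

    Returns a dict with the shared ``stack``, per-algorithm ``results``
    (:class:`ReconResult`), ``reports`` (:class:`MetricsReport`) and
    per-iteration amplitude / phase RMSE ``traces``.  When an output
    directory is configured, a CSV table, JSON reports and the resolved
    configuration are written there.
    """
    coeffs = sample_random_coeffs(spec.aberration_seed,
                                  jmax=spec.aberration_jmax,
                                  bound=spec.aberration_bound)
    stack = simulate_dataset(spec.scene, spec.geometry, coeffs)
    truth = stack.truth_object

    results: dict[str, ReconResult] = {}
    reports: dict[str, MetricsReport] = {}
    traces: dict[str, dict[str, list[float]]] = {}

    for algo in spec.algorithms:
        config = ReconConfig(algorithm=algo,
                             max_iterations=spec.max_iterations,
                             tolerance=spec.tolerance)
        trace_a: list[float] = []
        trace_p: list[float] = []

        def track(state) -> None:
            fld = ifft2c(state.spectrum)
            aligned, _ = align_to_truth(fld, truth.complex, upsample=10)
            trace_a.append(rmse_image(np.abs(aligned), truth.amplitude))
            trace_p.append(rmse_image(np.angle(aligned), truth.phase, "phase"))

        result = run_reconstruction(stack, config, iteration_callback=track)
        results[algo] = result
        reports[algo] = evaluate(result, stack)
        traces[algo] = {"amplitude_rmse": trace_a, "phase_rmse": trace_p}

    out = {"stack": stack, "results": results, "reports": reports,
           "traces": traces, "coeffs": coeffs}
    if spec.output_dir is not None:
        _write_outputs(spec, out)
    return out


def _write_outputs(spec: ExperimentSpec, out: dict) -> None:
    stamp = time.strftime("%Y%m%d-%H%M%S")
    root = Path(spec.output_dir) / f"benchmark-{stamp}"
    root.mkdir(parents=True, exist_ok=True)
    with open(root / "config.yaml", "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh)
    with open(root / "table.csv", "w") as fh:
        fh.write(MetricsReport.csv_header() + "\n")
        for rep in out["reports"].values():
            fh.write(rep.to_csv_row() + "\n")
    with open(root / "reports.json", "w") as fh:
        json.dump({a: json.loads(r.to_json())
                   for a, r in out["reports"].items()}, fh, indent=2)
    with open(root / "traces.json", "w") as fh:
        json.dump(out["traces"], fh, indent=2)
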