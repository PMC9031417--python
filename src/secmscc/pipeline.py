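"""End-to-end measurement pipeline and simulation-backed calibration.

``run_pipeline`` chains the analysis stages on one trace: trace -> per-cycle
|dI| -> dC -> respiration rate -> cell-count estimate -> mastitis category,
returning a JSON-serialisable report with provenance. Any stage failure is
re-raised as :class:`~secmscc.exceptions.PipelineStageError` naming the
stage.

``simulate_calibration_points`` closes the loop for testing and
demonstration: it forward-simulates traces at known concentrations and
processes them into calibration points, so a calibration fitted on simulator
output can be checked against the configured ground truth.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence

from . import __version__
from .calibration import (
    CalibrationCurve,
    CalibrationPoint,
    classify_mastitis,
    estimate_cell_count,
)
from .config import PipelineConfig, config_hash
from .exceptions import PipelineStageError
from .physics import respiration_from_delta_i
from .scans import DeltaIResult, ScanTrace, compute_delta_i
from .simulate import SimulationConfig, simulate_z_scan

__all__ = ["run_pipeline", "simulate_calibration_points"]


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


def run_pipeline(
    config: PipelineConfig,
    trace: ScanTrace,
    curve: Optional[CalibrationCurve] = None,
    seed: Optional[int] = None,
) -> Dict:
    """Process one trace into a full diagnosis report.

    Without a calibration curve the report stops after the physics
    (|dI|, dC, F); with one it adds the estimated somatic cell count and its
    mastitis category under the config's thresholds. ``seed`` is recorded in
    the provenance block when the trace came from the simulator.
    """
    result: DeltaIResult = _stage("scan_processing", compute_delta_i, trace)
    resp = _stage(
        "physical_model",
        respiration_from_delta_i,
        result.mean_abs_delta_i_pA,
        config.geometry,
        config.constants,
    )
    report: Dict = {
        "delta_i": {
            "per_cycle_pA": list(result.per_cycle_delta_i_pA),
            "mean_abs_pA": result.mean_abs_delta_i_pA,
            "sd_pA": result.sd_delta_i_pA,
            "excluded_initial": result.excluded_initial,
        },
        "delta_c_uM": resp.delta_C_uM,
        "respiration_rate_mol_s": resp.total_rate_F_mol_s,
        "provenance": {
            "config_sha256": config_hash(config),
            "package_version": __version__,
            "seed": seed,
        },
    }
    if curve is not None:
        low, high = config.thresholds_cells_per_ml
        cells = _stage(
            "calibration_diagnosis",
            estimate_cell_count,
            curve,
            result.mean_abs_delta_i_pA,
        )
        diagnosis = _stage("calibration_diagnosis", classify_mastitis, cells, low, high)
        report["estimated_cells_per_ml"] = diagnosis.estimated_cells_per_ml
        report["category"] = diagnosis.category.value
        report["thresholds_cells_per_ml"] = [low, high]
    return report


def simulate_calibration_points(
    concentrations_per_ml: Sequence[float],
    base_config: SimulationConfig,
    reading: str = "extrapolate",
) -> List[CalibrationPoint]:
    """Forward-simulate and process one trace per concentration.

    Each point gets an independent noise stream (seed offset by its index)
    while the physics and protocol come from ``base_config``.
    """
    points = []
    for i, n in enumerate(concentrations_per_ml):
        cfg = dataclasses.replace(
            base_config,
            cell_concentration_per_ml=float(n),
            seed=base_config.seed + i,
        )
        res = compute_delta_i(simulate_z_scan(cfg), reading=reading)
        points.append(
            CalibrationPoint(
                cells_per_ml=float(n),
                mean_abs_delta_i_pA=res.mean_abs_delta_i_pA,
                sd_delta_i_pA=res.sd_delta_i_pA,
            )
        )
    return points
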