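"""Readers and writers for the package's plain-text formats.

* Trace CSV: header ``time_s,height_um,current_nA`` (``height_um`` optional).
* Image CSV: a bare rectangular matrix of currents in nA, with a JSON
  sidecar carrying ``pixel_size_um``, ``z_prime_um`` and ``origin_um``.
* Calibration CSV: header ``cells_per_ml,delta_i_pA`` with optional ``sd_pA``.
* Curve JSON: the fitted calibration coefficients.

Writers emit exactly the dialect the readers consume, so write-then-read is
an identity up to float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, CalibrationPoint
from .exceptions import FormatError
from .imaging import CurrentImage
from .scans import ScanProtocol, ScanTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_image",
    "write_image",
    "read_calibration_points",
    "write_calibration_points",
    "read_curve",
    "write_curve",
]

PathLike = Union[str, Path]


def _read_csv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_trace(path: PathLike, protocol: ScanProtocol) -> ScanTrace:
    """Read a z-scan trace CSV; the protocol comes from config, not the file."""
    df = _read_csv(path, required=["time_s", "current_nA"])
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) < 2:
        raise FormatError(f"{path}: a trace needs at least 2 samples")
    if not np.all(np.diff(times) > 0):
        raise FormatError(f"{path}: time_s must be strictly increasing")
    heights = (
        df["height_um"].to_numpy(dtype=float) if "height_um" in df.columns else None
    )
    return ScanTrace(
        times_s=times,
        currents_nA=df["current_nA"].to_numpy(dtype=float),
        protocol=protocol,
        heights_um=heights,
    )


def write_trace(trace: ScanTrace, path: PathLike) -> None:
    cols = {"time_s": trace.times_s}
    if trace.heights_um is not None:
        cols["height_um"] = trace.heights_um
    cols["current_nA"] = trace.currents_nA
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def _meta_path(csv_path: PathLike) -> Path:
    return Path(csv_path).with_suffix(".json")


def read_image(csv_path: PathLike, meta_path: Optional[PathLike] = None) -> CurrentImage:
    """Read an image CSV plus its JSON sidecar (defaults to ``<image>.json``)."""
    meta_path = Path(meta_path) if meta_path else _meta_path(csv_path)
    if not meta_path.exists():
        raise FormatError(f"image metadata sidecar {meta_path} not found")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{meta_path}: not valid JSON ({exc})") from exc
    for key in ("pixel_size_um", "z_prime_um"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing key '{key}'")
    try:
        currents = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{csv_path}: cannot parse image matrix ({exc})") from exc
    origin = tuple(meta.get("origin_um", (0.0, 0.0)))
    return CurrentImage(
        currents_nA=currents,
        pixel_size_um=float(meta["pixel_size_um"]),
        z_prime_um=float(meta["z_prime_um"]),
        origin_um=origin,
    )


def write_image(
    image: CurrentImage, csv_path: PathLike, meta_path: Optional[PathLike] = None
) -> None:
    np.savetxt(csv_path, image.currents_nA, delimiter=",", fmt="%.9g")
    meta = {
        "pixel_size_um": image.pixel_size_um,
        "z_prime_um": image.z_prime_um,
        "origin_um": list(image.origin_um),
    }
    (Path(meta_path) if meta_path else _meta_path(csv_path)).write_text(
        json.dumps(meta, indent=1)
    )


def read_calibration_points(path: PathLike) -> List[CalibrationPoint]:
    df = _read_csv(path, required=["cells_per_ml", "delta_i_pA"])
    points = []
    for _, row in df.iterrows():
        sd = float(row["sd_pA"]) if "sd_pA" in df.columns and pd.notna(row.get("sd_pA")) else None
        points.append(
            CalibrationPoint(
                cells_per_ml=float(row["cells_per_ml"]),
                mean_abs_delta_i_pA=float(row["delta_i_pA"]),
                sd_delta_i_pA=sd,
            )
        )
    if not points:
        raise FormatError(f"{path}: no calibration points")
    return points


def write_calibration_points(points: Sequence[CalibrationPoint], path: PathLike) -> None:
    pd.DataFrame(
        {
            "cells_per_ml": [p.cells_per_ml for p in points],
            "delta_i_pA": [p.mean_abs_delta_i_pA for p in points],
            "sd_pA": [p.sd_delta_i_pA for p in points],
        }
    ).to_csv(path, index=False, float_format="%.9g")


def write_curve(curve: CalibrationCurve, path: PathLike) -> None:
    doc = {
        "slope_pA_per_cells_ml": curve.slope_pA_per_cells_ml,
        "intercept_pA": curve.intercept_pA,
        "r_squared": curve.r_squared,
        "n_points": curve.n_points,
        "valid_range_cells_per_ml": list(curve.valid_range_cells_per_ml),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_curve(path: PathLike) -> CalibrationCurve:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return CalibrationCurve(
            slope_pA_per_cells_ml=float(doc["slope_pA_per_cells_ml"]),
            intercept_pA=float(doc["intercept_pA"]),
            r_squared=float(doc["r_squared"]),
            n_points=int(doc["n_points"]),
            valid_range_cells_per_ml=tuple(doc["valid_range_cells_per_ml"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing curve key {exc}") from exc
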