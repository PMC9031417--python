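"""JSON configuration documents.

A pipeline config bundles the medium constants, port geometry, scan protocol
and classification thresholds. Unknown keys are rejected with a message
naming them - silent typos in physical constants are worse than a hard
failure. All constants default to the milk-cell-chip values; a protocol (or
the constants) may also be given as a named preset string ("chip" or
"cone").

Example document::

    {
      "constants": {"diffusion_coefficient_cm2_s": 2.18e-5,
                    "bulk_oxygen_uM": 248.0,
                    "bulk_current_nA": -1.7},
      "geometry":  {"port_side_um": 200.0,
                    "equivalent_radius_um": 100.0,
                    "well_volume_uL": 1.5,
                    "cell_fraction": 0.1},
      "protocol":  "chip",
      "thresholds": {"low_cells_per_ml": 1.0e5, "high_cells_per_ml": 2.0e5}
    }
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, Mapping, Tuple, Union

from .calibration import THRESHOLD_PRESETS
from .exceptions import ConfigError
from .physics import MediumConstants, PortGeometry
from .scans import ScanProtocol

__all__ = ["PipelineConfig", "load_config", "config_hash"]

_SECTIONS = ("constants", "geometry", "protocol", "thresholds")


def _build(cls, section: Mapping[str, Any], name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{name}': {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


def _protocol_from(value: Union[str, Mapping[str, Any]]) -> ScanProtocol:
    if isinstance(value, str):
        presets = {"chip": ScanProtocol.chip, "cone": ScanProtocol.cone_well}
        if value not in presets:
            raise ConfigError(
                f"unknown protocol preset {value!r}; use one of {sorted(presets)}"
            )
        return presets[value]()
    return _build(ScanProtocol, value, "protocol")


def _thresholds_from(value: Union[str, Mapping[str, Any]]) -> Tuple[float, float]:
    if isinstance(value, str):
        if value not in THRESHOLD_PRESETS:
            raise ConfigError(
                f"unknown threshold preset {value!r}; use one of "
                f"{sorted(THRESHOLD_PRESETS)}"
            )
        return THRESHOLD_PRESETS[value]
    allowed = {"low_cells_per_ml", "high_cells_per_ml"}
    unknown = set(value) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in 'thresholds': {sorted(unknown)}")
    low = float(value.get("low_cells_per_ml", 1.0e5))
    high = float(value.get("high_cells_per_ml", 2.0e5))
    if not 0 < low < high:
        raise ConfigError("thresholds must satisfy 0 < low < high")
    return (low, high)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated bundle of everything a pipeline run needs."""

    constants: MediumConstants = MediumConstants.chip()
    geometry: PortGeometry = PortGeometry.chip()
    protocol: ScanProtocol = ScanProtocol.chip()
    thresholds_cells_per_ml: Tuple[float, float] = (1.0e5, 2.0e5)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(doc) - set(_SECTIONS)
        if unknown:
            raise ConfigError(
                f"unknown top-level key(s): {sorted(unknown)}; "
                f"allowed: {sorted(_SECTIONS)}"
            )
        kwargs: Dict[str, Any] = {}
        if "constants" in doc:
            kwargs["constants"] = _build(MediumConstants, doc["constants"], "constants")
        if "geometry" in doc:
            kwargs["geometry"] = _build(PortGeometry, doc["geometry"], "geometry")
        if "protocol" in doc:
            kwargs["protocol"] = _protocol_from(doc["protocol"])
        if "thresholds" in doc:
            kwargs["thresholds_cells_per_ml"] = _thresholds_from(doc["thresholds"])
        return cls(**kwargs)

    def to_dict(self) -> Dict[str, Any]:
        return {
            "constants": dataclasses.asdict(self.constants),
            "geometry": dataclasses.asdict(self.geometry),
            "protocol": dataclasses.asdict(self.protocol),
            "thresholds": {
                "low_cells_per_ml": self.thresholds_cells_per_ml[0],
                "high_cells_per_ml": self.thresholds_cells_per_ml[1],
            },
        }


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Read and validate a JSON pipeline config."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config document must be a JSON object")
    return PipelineConfig.from_dict(doc)


def config_hash(config: PipelineConfig) -> str:
    """Stable sha256 of the canonical JSON form (for report provenance)."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()
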