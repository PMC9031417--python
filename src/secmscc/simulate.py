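"""Physics-based forward simulator of the measurement.

The generative chain is the analysis chain run forwards: a known number of
cells in the well, each consuming oxygen at a constant per-cell rate, sets a
total respiration rate F; inverting the hemispherical rate equation gives
the steady-state depletion field; the electrode trajectory samples that
field; the reduction current at height r is ``I(r) = I_bulk * C(r) / C*``.
On top of the noiseless backbone the simulator can inject

* additive white Gaussian current noise (seeded),
* a settling transient - currents in the first 5% of the first leg scaled up
  by ``settling_excess`` (default 20%), emulating scanning started right
  after the working potential is applied,
* multiplicative electrode fouling - an exponential sensitivity decay
  calibrated by the fraction of signal retained after 10 minutes (about 10%
  for a bare electrode in milk, about 99% with collagen embedding),
* a respiratory-burst factor multiplying the per-cell rate (PMA-stimulated
  immune cells consume roughly fivefold more oxygen).

Everything is deterministic given the seed, and every generated artefact has
a closed-form expectation (``expected_delta_i``, ``isosurface_distance``) so
the analysis modules can be verified against the generator analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .exceptions import DomainError
from .imaging import CurrentImage
from .physics import (
    DiffusionField,
    MediumConstants,
    PortGeometry,
    surface_concentration_from_rate,
)
from .scans import ScanProtocol, ScanTrace
from .units import UL_TO_ML

__all__ = [
    "FoulingModel",
    "SimulationConfig",
    "fouling_sensitivity",
    "total_respiration_rate",
    "field_from_cells",
    "expected_delta_i",
    "isosurface_distance",
    "simulate_z_scan",
    "simulate_xy_scan",
    "simulate_z_profile",
]

#: reference time at which the retained sensitivity fraction is specified
FOULING_REFERENCE_S = 600.0


@dataclass(frozen=True)
class FoulingModel:
    """Exponential electrode-sensitivity decay s(t).

    ``s(0) = 1`` and ``s(600 s) = retained_fraction_at_10min``; mode "none"
    keeps sensitivity at 1. The bare-electrode default retains 10% after ten
    minutes in milk; collagen embedding retains 99%.
    """

    mode: str = "none"
    retained_fraction_at_10min: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "bare", "collagen"):
            raise DomainError("fouling mode must be none, bare or collagen")
        if not 0 < self.retained_fraction_at_10min <= 1:
            raise DomainError("retained fraction must be in (0, 1]")
        if self.mode == "none" and self.retained_fraction_at_10min != 1.0:
            raise DomainError("mode 'none' implies full retention")

    @classmethod
    def none(cls) -> "FoulingModel":
        return cls("none", 1.0)

    @classmethod
    def bare(cls, retained: float = 0.10) -> "FoulingModel":
        return cls("bare", retained)

    @classmethod
    def collagen(cls, retained: float = 0.99) -> "FoulingModel":
        return cls("collagen", retained)

    def sensitivity(self, t_s):
        """s(t), scalar or array, for t >= 0."""
        t = np.asarray(t_s, dtype=float)
        if np.any(t < 0):
            raise DomainError("time must be >= 0")
        rate = -math.log(self.retained_fraction_at_10min) / FOULING_REFERENCE_S
        s = np.exp(-rate * t)
        return float(s) if np.isscalar(t_s) else s


def fouling_sensitivity(model: FoulingModel, t_s):
    """Sensitivity multiplier s(t); s(0) = 1, s(600) = retained fraction."""
    return model.sensitivity(t_s)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete generative description of one synthetic measurement.

    Defaults reproduce the milk-cell-chip conditions: 1.5 uL well loaded
    with a 1:9 cell/collagen mix behind a 200 x 200 um port (equivalent
    hemisphere radius 100 um), oxygen-saturated PBS (248 uM, D = 2.18e-5
    cm^2/s, bulk current -1.7 nA), the 500 um / 50 um/s / 3-cycle z-scan
    protocol, a per-cell respiration rate of 1.4e-16 mol/s, 2 pA current
    noise, a 20% settling excess at the start of the scan, and no fouling.
    """

    cell_concentration_per_ml: float
    per_cell_rate_mol_s: float = 1.4e-16
    burst_factor: float = 1.0
    geometry: PortGeometry = PortGeometry.chip()
    constants: MediumConstants = MediumConstants.chip()
    protocol: ScanProtocol = ScanProtocol.chip()
    noise_sd_pA: float = 2.0
    settling_excess: float = 0.20
    fouling: FoulingModel = FoulingModel.none()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_concentration_per_ml < 0:
            raise DomainError("cell_concentration_per_ml must be >= 0")
        if self.per_cell_rate_mol_s < 0:
            raise DomainError("per_cell_rate_mol_s must be >= 0")
        if self.burst_factor < 1:
            raise DomainError("burst_factor must be >= 1 (1 = no burst)")
        if self.noise_sd_pA < 0:
            raise DomainError("noise_sd_pA must be >= 0")
        if self.settling_excess < 0:
            raise DomainError("settling_excess must be >= 0")


def total_respiration_rate(config: SimulationConfig) -> float:
    """Well-total oxygen consumption F (mol/s) implied by the config."""
    n_cells = (
        config.cell_concentration_per_ml
        * config.geometry.well_volume_uL
        * UL_TO_ML
        * config.geometry.cell_fraction
    )
    return n_cells * config.per_cell_rate_mol_s * config.burst_factor


def field_from_cells(config: SimulationConfig) -> DiffusionField:
    """Steady-state depletion field generated by the configured cells.

    Raises :class:`~secmscc.exceptions.InfeasibleRateError` when the cells
    would demand more oxygen than the hemispherical steady state can supply
    (surface concentration would go negative).
    """
    return surface_concentration_from_rate(
        total_respiration_rate(config), config.geometry, config.constants
    )


def expected_delta_i(config: SimulationConfig) -> float:
    """Analytic surface-bulk |dI| (pA) of a noiseless, fouling-free scan.

    The surface reading is taken at the protocol's surface offset and the
    bulk reading one scan span higher, exactly where the turnarounds sit:

        |dI| = |I_bulk| * (dC / C*) * (r_s/(r_s+r_surf) - r_s/(r_s+r_bulk))
    """
    fld = field_from_cells(config)
    rs = config.geometry.equivalent_radius_um
    r_surf = config.protocol.surface_offset_um
    r_bulk = r_surf + config.protocol.scan_span_um
    geom = rs / (rs + r_surf) - rs / (rs + r_bulk)
    return (
        abs(config.constants.bulk_current_nA)
        * 1000.0
        * (fld.delta_C_uM / config.constants.bulk_oxygen_uM)
        * geom
    )


def isosurface_distance(config: SimulationConfig, threshold_nA: float) -> Optional[float]:
    """Distance from the port at which |I| equals |threshold| (um).

    This is the radius of the threshold isosurface of the hemispherical
    field. Returns None when the field never reaches the threshold (too
    little depletion) or the threshold magnitude exceeds the bulk current.
    """
    fld = field_from_cells(config)
    cstar = config.constants.bulk_oxygen_uM
    ratio = abs(threshold_nA) / abs(config.constants.bulk_current_nA)
    if ratio >= 1 or fld.delta_C_uM == 0:
        return None
    needed = cstar * (1.0 - ratio)  # depletion required at the isosurface
    rs = config.geometry.equivalent_radius_um
    if fld.delta_C_uM < needed:
        return None
    return fld.delta_C_uM * rs / needed - rs


def _triangular_heights(protocol: ScanProtocol, times_s: np.ndarray) -> np.ndarray:
    """Electrode height above the sample for a reciprocating scan."""
    L = protocol.leg_duration_s
    phase = np.mod(times_s, 2.0 * L) / L
    frac = np.where(phase <= 1.0, phase, 2.0 - phase)
    if not protocol.starts_at_surface:
        frac = 1.0 - frac
    return protocol.surface_offset_um + protocol.scan_span_um * frac


def simulate_z_scan(config: SimulationConfig) -> ScanTrace:
    """Forward-simulate one z-scan current trace.

    Triangular height trajectory per the protocol; noiseless current from
    the steady-state field; then, in order: settling excess on the first 5%
    of the first leg, multiplicative fouling sensitivity, additive Gaussian
    noise. Deterministic given ``config.seed``.
    """
    p = config.protocol
    n = int(round(p.total_duration_s / p.sampling_interval_s)) + 1
    times = np.arange(n) * p.sampling_interval_s
    heights = _triangular_heights(p, times)
    fld = field_from_cells(config)
    currents = fld.current_at(heights)
    if config.settling_excess > 0:
        currents = np.where(
            times < 0.05 * p.leg_duration_s,
            currents * (1.0 + config.settling_excess),
            currents,
        )
    currents = currents * config.fouling.sensitivity(times)
    if config.noise_sd_pA > 0:
        rng = np.random.default_rng(config.seed)
        currents = currents + rng.normal(0.0, config.noise_sd_pA * 1e-3, size=n)
    return ScanTrace(
        times_s=times, currents_nA=currents, protocol=p, heights_um=heights
    )


def simulate_xy_scan(
    config: SimulationConfig,
    z_prime_um: float,
    extent_um: Tuple[float, float] = (300.0, 500.0),
    pixel_um: float = 10.0,
    center_um: Optional[Tuple[float, float]] = None,
) -> CurrentImage:
    """Forward-simulate an XY raster image at electrode height Z'.

    The hemispherical field is defined on-axis by R = r_s + r; off-axis the
    same law is applied with r replaced by the Euclidean distance from the
    port centre (in the chip plane) to the electrode tip, so the field is
    radially symmetric about the port and reduces to the z-scan current on
    axis. The port centre defaults to the image centre. Gaussian pixel noise
    is seeded from ``config.seed``.
    """
    if pixel_um <= 0 or extent_um[0] <= 0 or extent_um[1] <= 0:
        raise DomainError("pixel size and extents must be > 0")
    if z_prime_um < 0:
        raise DomainError("z_prime_um must be >= 0")
    fld = field_from_cells(config)
    x = np.arange(0.0, extent_um[0] + pixel_um / 2, pixel_um)
    y = np.arange(0.0, extent_um[1] + pixel_um / 2, pixel_um)
    cx, cy = center_um if center_um is not None else (extent_um[0] / 2, extent_um[1] / 2)
    xx, yy = np.meshgrid(x - cx, y - cy)
    dist = np.sqrt(xx**2 + yy**2 + z_prime_um**2)
    currents = fld.current_at(dist)
    if config.noise_sd_pA > 0:
        rng = np.random.default_rng(config.seed)
        currents = currents + rng.normal(0.0, config.noise_sd_pA * 1e-3, currents.shape)
    return CurrentImage(
        currents_nA=currents,
        pixel_size_um=pixel_um,
        z_prime_um=z_prime_um,
        origin_um=(0.0, 0.0),
    )


def simulate_z_profile(
    config: SimulationConfig,
    distances_um,
    noisy: bool = False,
) -> np.ndarray:
    """Stepwise vertical profile: current (nA) at each electrode height.

    Mirrors the protocol used to find the minimum bulk distance: the
    electrode pauses at each height and the settled current is recorded.
    """
    fld = field_from_cells(config)
    currents = fld.current_at(np.asarray(distances_um, dtype=float))
    if noisy and config.noise_sd_pA > 0:
        rng = np.random.default_rng(config.seed)
        currents = currents + rng.normal(0.0, config.noise_sd_pA * 1e-3, currents.shape)
    return currents
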