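"""Electrochemical and diffusion physics of the measurement.

A platinum microelectrode held at an oxygen-reduction potential reports the
local dissolved-oxygen concentration as a (negative, cathodic) reduction
current proportional to concentration: ``I = I_bulk * C / C*``. Somatic cells
confined behind a square detection port consume oxygen and, in steady state,
draw a hemispherical depletion field out of the bulk. With the port
represented by an equivalent hemisphere of radius ``r_s``, the total oxygen
consumption rate is

    F = 2 * pi * r_s * D * (C* - C_s)          [mol/s]

where ``D`` is the oxygen diffusion coefficient, ``C*`` the bulk oxygen
concentration and ``C_s`` the concentration at the port surface. The
steady-state profile along the distance ``r`` above the port is

    C(r) = C* - (C* - C_s) * r_s / (r_s + r)

This module holds the constants, the forward and inverse forms of the rate
equation, the concentration profile, and the per-cell normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .exceptions import DomainError, InfeasibleRateError
from .units import UL_TO_ML, um_to_cm, uM_to_mol_per_cm3, mol_per_cm3_to_uM

__all__ = [
    "MediumConstants",
    "PortGeometry",
    "DiffusionField",
    "RespirationResult",
    "current_to_concentration",
    "respiration_rate",
    "respiration_rate_cgs",
    "surface_concentration_from_rate",
    "concentration_at",
    "current_at",
    "per_cell_rate",
    "respiration_from_delta_i",
]


@dataclass(frozen=True)
class MediumConstants:
    """Physical constants of the measurement solution.

    Parameters
    ----------
    diffusion_coefficient_cm2_s
        Oxygen diffusion coefficient ``D`` in cm^2/s.
    bulk_oxygen_uM
        Bulk dissolved-oxygen concentration ``C*`` in uM.
    bulk_current_nA
        Oxygen reduction current measured in bulk, signed (negative for a
        cathodic reduction current), in nA.
    temperature_C
        Annotation only; no temperature model is applied.
    """

    diffusion_coefficient_cm2_s: float = 2.18e-5
    bulk_oxygen_uM: float = 248.0
    bulk_current_nA: float = -1.7
    temperature_C: Optional[float] = 25.0

    def __post_init__(self) -> None:
        if not self.diffusion_coefficient_cm2_s > 0:
            raise DomainError("diffusion_coefficient_cm2_s must be > 0")
        if not self.bulk_oxygen_uM > 0:
            raise DomainError("bulk_oxygen_uM must be > 0")
        if self.bulk_current_nA == 0:
            raise DomainError("bulk_current_nA must be nonzero")

    @classmethod
    def cone_well(cls) -> "MediumConstants":
        """Constants for measurements in the inverted cone-shaped well
        (bulk reference current -1.76 nA at room temperature)."""
        return cls(bulk_current_nA=-1.76, temperature_C=None)

    @classmethod
    def chip(cls) -> "MediumConstants":
        """Constants for measurements on the silicon milk-cell chip
        (bulk reference current -1.7 nA at 25 degC)."""
        return cls(bulk_current_nA=-1.7, temperature_C=25.0)


@dataclass(frozen=True)
class PortGeometry:
    """Geometry of the detection port and sample well.

    The square detection port (side ``port_side_um``) is modelled as a
    hemisphere of equivalent radius ``equivalent_radius_um``; the default is
    half the port side. ``cell_fraction`` is the volume fraction of cell
    suspension in the collagen mix loaded into the well (1:9 mix -> 0.1).
    """

    port_side_um: float = 200.0
    equivalent_radius_um: float = 100.0
    well_volume_uL: float = 1.5
    cell_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not self.equivalent_radius_um > 0:
            raise DomainError("equivalent_radius_um must be > 0")
        if not (0 < self.cell_fraction <= 1):
            raise DomainError("cell_fraction must be in (0, 1]")
        if not self.well_volume_uL > 0:
            raise DomainError("well_volume_uL must be > 0")

    @classmethod
    def chip(cls) -> "PortGeometry":
        return cls()


@dataclass(frozen=True)
class DiffusionField:
    """Steady-state hemispherical oxygen field over a detection port.

    Stores the depletion depth ``delta_C = C* - C_s`` directly (it is the
    quantity every equation uses, and deriving it from ``C_s`` would lose
    precision for weak fields); the surface concentration is derived so the
    identity ``C_s = C* - delta_C`` holds exactly.
    """

    constants: MediumConstants
    geometry: PortGeometry
    delta_C_uM: float

    def __post_init__(self) -> None:
        if not (0 <= self.delta_C_uM <= self.constants.bulk_oxygen_uM):
            raise DomainError(
                "depletion depth must lie in [0, C*]; got "
                f"{self.delta_C_uM} uM with C* = {self.constants.bulk_oxygen_uM} uM"
            )

    @property
    def surface_concentration_uM(self) -> float:
        """Oxygen concentration at the port surface, C_s = C* - delta_C."""
        return self.constants.bulk_oxygen_uM - self.delta_C_uM

    def concentration_at(self, distance_r_um):
        """Oxygen concentration (uM) at distance ``r`` above the port.

        Accepts a scalar or array. C(0) = C_s; C -> C* as r -> inf.
        """
        r = np.asarray(distance_r_um, dtype=float)
        if np.any(r < 0):
            raise DomainError("distance above the port must be >= 0")
        rs = self.geometry.equivalent_radius_um
        c = self.constants.bulk_oxygen_uM - self.delta_C_uM * rs / (rs + r)
        return float(c) if np.isscalar(distance_r_um) else c

    def current_at(self, distance_r_um):
        """Reduction current (nA, signed) the electrode reads at ``r``."""
        c = self.concentration_at(distance_r_um)
        return self.constants.bulk_current_nA * c / self.constants.bulk_oxygen_uM


@dataclass(frozen=True)
class RespirationResult:
    """Respiration-rate analysis of one measured |dI|."""

    delta_i_pA: float
    delta_C_uM: float
    total_rate_F_mol_s: float
    per_cell_rate_mol_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.total_rate_F_mol_s < 0:
            raise DomainError("total respiration rate must be >= 0")
        if self.per_cell_rate_mol_s is not None and self.per_cell_rate_mol_s < 0:
            raise DomainError("per-cell rate must be >= 0")


def current_to_concentration(delta_i_pA: float, constants: MediumConstants) -> float:
    """Convert a surface-bulk current difference |dI| to a concentration
    difference dC = C* - C_s.

    The reduction current is proportional to oxygen concentration, so
    ``dC = (|dI| / |I_bulk|) * C*``.

    Parameters
    ----------
    delta_i_pA
        Magnitude of the current difference, pA (must be >= 0).
    constants
        Medium constants supplying ``C*`` and the bulk reference current.

    Returns
    -------
    float
        dC in uM.
    """
    if delta_i_pA < 0:
        raise DomainError("delta_i_pA is a magnitude and must be >= 0")
    bulk_pA = abs(constants.bulk_current_nA) * 1000.0
    return (delta_i_pA / bulk_pA) * constants.bulk_oxygen_uM


def respiration_rate_cgs(delta_c_mol_cm3: float, r_s_cm: float, d_cm2_s: float) -> float:
    """F = 2*pi*r_s*D*dC with all arguments in CGS units (mol/s)."""
    if delta_c_mol_cm3 < 0:
        raise DomainError("delta_C must be >= 0")
    if r_s_cm <= 0 or d_cm2_s <= 0:
        raise DomainError("r_s and D must be > 0")
    return 2.0 * math.pi * r_s_cm * d_cm2_s * delta_c_mol_cm3


def respiration_rate(
    delta_c_uM: float, geometry: PortGeometry, constants: MediumConstants
) -> float:
    """Total oxygen consumption rate F (mol/s) from a depletion depth.

    Evaluates F = 2*pi*r_s*D*(C* - C_s) with dC = C* - C_s given in uM,
    ``r_s`` taken from the geometry (um) and ``D`` from the constants
    (cm^2/s); both are converted internally to CGS.
    """
    return respiration_rate_cgs(
        uM_to_mol_per_cm3(delta_c_uM),
        um_to_cm(geometry.equivalent_radius_um),
        constants.diffusion_coefficient_cm2_s,
    )


def surface_concentration_from_rate(
    total_rate_F_mol_s: float, geometry: PortGeometry, constants: MediumConstants
) -> DiffusionField:
    """Invert the rate equation: the field whose steady state supplies F.

    dC = F / (2*pi*r_s*D). Raises :class:`InfeasibleRateError` when the
    demanded rate would push the surface concentration below zero, i.e. the
    hemispherical steady state cannot deliver that much oxygen.
    """
    if total_rate_F_mol_s < 0:
        raise DomainError("respiration rate must be >= 0")
    denom = (
        2.0
        * math.pi
        * um_to_cm(geometry.equivalent_radius_um)
        * constants.diffusion_coefficient_cm2_s
    )
    delta_c_uM = mol_per_cm3_to_uM(total_rate_F_mol_s / denom)
    if delta_c_uM > constants.bulk_oxygen_uM:
        raise InfeasibleRateError(
            f"rate {total_rate_F_mol_s:.3e} mol/s needs dC = {delta_c_uM:.1f} uM "
            f"but bulk oxygen is only {constants.bulk_oxygen_uM:.1f} uM"
        )
    return DiffusionField(constants, geometry, delta_C_uM=delta_c_uM)


def concentration_at(field: DiffusionField, distance_r_um):
    """Oxygen concentration (uM) at distance ``r`` (um) above the port."""
    return field.concentration_at(distance_r_um)


def current_at(field: DiffusionField, distance_r_um):
    """Reduction current (nA, signed) at distance ``r`` (um) above the port."""
    return field.current_at(distance_r_um)


def per_cell_rate(
    total_rate_F_mol_s: float,
    cell_concentration_per_ml: float,
    geometry: PortGeometry,
) -> float:
    """Respiration rate per cell (mol/s/cell).

    Divides the well total F by the number of cells actually in the well:
    ``cell_concentration * well_volume * cell_fraction`` (the suspension is
    diluted 1:9 into collagen before loading, hence the fraction).
    """
    if total_rate_F_mol_s < 0:
        raise DomainError("total respiration rate must be >= 0")
    if cell_concentration_per_ml <= 0:
        raise DomainError(
            "cell_concentration_per_ml must be > 0 to normalise per cell "
            f"(got {cell_concentration_per_ml})"
        )
    n_cells = (
        cell_concentration_per_ml
        * geometry.well_volume_uL
        * UL_TO_ML
        * geometry.cell_fraction
    )
    return total_rate_F_mol_s / n_cells


def respiration_from_delta_i(
    delta_i_pA: float,
    geometry: PortGeometry,
    constants: MediumConstants,
    cell_concentration_per_ml: Optional[float] = None,
) -> RespirationResult:
    """Full chain |dI| -> dC -> F (-> per-cell rate when N is known)."""
    dc = current_to_concentration(delta_i_pA, constants)
    f = respiration_rate(dc, geometry, constants)
    pcr = (
        per_cell_rate(f, cell_concentration_per_ml, geometry)
        if cell_concentration_per_ml
        else None
    )
    return RespirationResult(
        delta_i_pA=delta_i_pA,
        delta_C_uM=dc,
        total_rate_F_mol_s=f,
        per_cell_rate_mol_s=pcr,
    )
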