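"""XY raster images of the oxygen-reduction current and the diffusion-layer
geometry read off them.

An image taken at electrode height Z' above the chip shows a roughly circular
patch of reduced |current| over the detection port. A line profile along y at
fixed x crosses that patch; half the extent over which the depletion exceeds
a current threshold is the half-width L. For a hemispherical depletion layer
whose threshold isosurface has radius rho, the imaging plane cuts it in a
circle of radius sqrt(rho^2 - Z'^2), so the isosurface radius is recovered by
Pythagoras:

    r' = sqrt(L^2 + Z'^2)

Agreement of r' across imaging heights is the operational check that the
layer really is hemispherical. The module also finds, from a stepwise
z-profile, the distance beyond which the current stops changing - the
minimum height that can serve as the "bulk" position of a z-scan.

Threshold convention: reduction currents are negative and depletion makes
them smaller in magnitude, so a pixel is inside the layer when
``|current| <= |threshold|`` (e.g. -1.5 nA is outside a -1.4 nA threshold,
-1.2 nA is inside).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .exceptions import DomainError, InsufficientDataError

__all__ = [
    "CurrentImage",
    "LineProfile",
    "RadiusEstimate",
    "extract_line_profile",
    "half_width_at_threshold",
    "diffusion_layer_radius",
    "estimate_radius",
    "hemisphericity_check",
    "z_profile_saturation",
]


@dataclass
class CurrentImage:
    """Rectangular grid of reduction currents at one electrode height.

    Rows index y, columns index x; grid index (i, j) maps to physical
    coordinates ``origin + index * pixel_size``.
    """

    currents_nA: np.ndarray
    pixel_size_um: float
    z_prime_um: float
    origin_um: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.currents_nA = np.atleast_2d(np.asarray(self.currents_nA, dtype=float))
        if self.currents_nA.ndim != 2:
            raise DomainError("currents must form a rectangular 2-D grid")
        if not self.pixel_size_um > 0:
            raise DomainError("pixel_size_um must be > 0")
        if self.z_prime_um < 0:
            raise DomainError("z_prime_um must be >= 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.currents_nA.shape

    @property
    def x_coords_um(self) -> np.ndarray:
        return self.origin_um[0] + np.arange(self.shape[1]) * self.pixel_size_um

    @property
    def y_coords_um(self) -> np.ndarray:
        return self.origin_um[1] + np.arange(self.shape[0]) * self.pixel_size_um

    def plot(self, ax=None):
        """Current map in nA (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        extent = [
            self.x_coords_um[0],
            self.x_coords_um[-1],
            self.y_coords_um[0],
            self.y_coords_um[-1],
        ]
        im = ax.imshow(self.currents_nA, origin="lower", extent=extent)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        plt.colorbar(im, ax=ax, label="current (nA)")
        return ax


@dataclass(frozen=True)
class LineProfile:
    """Current along one image column (fixed x)."""

    y_um: np.ndarray
    current_nA: np.ndarray

    def __len__(self) -> int:
        return len(self.y_um)


@dataclass(frozen=True)
class RadiusEstimate:
    """Diffusion-layer radius reconstructed from one image."""

    half_width_L_um: float
    z_prime_um: float
    radius_rprime_um: float
    threshold_nA: float

    def __post_init__(self) -> None:
        if self.radius_rprime_um + 1e-9 < max(self.half_width_L_um, self.z_prime_um):
            raise DomainError("r' must be at least as large as L and Z'")


def extract_line_profile(image: CurrentImage, x_index: int) -> LineProfile:
    """Column of currents at one x index, with physical y coordinates."""
    ncols = image.shape[1]
    if not (-ncols <= x_index < ncols):
        raise DomainError(f"x_index {x_index} outside image with {ncols} columns")
    return LineProfile(
        y_um=image.y_coords_um.copy(),
        current_nA=image.currents_nA[:, x_index].copy(),
    )


def half_width_at_threshold(profile: LineProfile, threshold_nA: float) -> float:
    """Half-width L (um) of the depleted span along the profile.

    A sample is inside the diffusion layer when its current magnitude is at
    most the threshold magnitude. L is half the distance between the
    outermost passing samples (an overall diameter; noise may split the run).
    Returns 0 with a warning when nothing passes.
    """
    if len(profile) == 0:
        raise InsufficientDataError("empty profile")
    mask = np.abs(profile.current_nA) <= abs(threshold_nA)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(
            f"no sample reaches the {threshold_nA} nA threshold; L = 0",
            stacklevel=2,
        )
        return 0.0
    return float(profile.y_um[idx[-1]] - profile.y_um[idx[0]]) / 2.0


def diffusion_layer_radius(half_width_L_um: float, z_prime_um: float) -> float:
    """Isosurface radius r' = sqrt(L^2 + Z'^2) (um)."""
    if half_width_L_um < 0 or z_prime_um < 0:
        raise DomainError("L and Z' must be >= 0")
    return math.hypot(half_width_L_um, z_prime_um)


def estimate_radius(
    image: CurrentImage, x_index: int, threshold_nA: float
) -> RadiusEstimate:
    """Half-width and Pythagorean radius from one image column."""
    L = half_width_at_threshold(extract_line_profile(image, x_index), threshold_nA)
    return RadiusEstimate(
        half_width_L_um=L,
        z_prime_um=image.z_prime_um,
        radius_rprime_um=diffusion_layer_radius(L, image.z_prime_um),
        threshold_nA=threshold_nA,
    )


def hemisphericity_check(estimates: Sequence[RadiusEstimate]) -> float:
    """Relative spread of r' across imaging heights.

    Returns ``(max r' - min r') / mean r'``; a small spread supports the
    hemispherical-layer assumption. Needs at least two estimates.
    """
    if len(estimates) < 2:
        raise InsufficientDataError("need >= 2 radius estimates at distinct heights")
    r = np.array([e.radius_rprime_um for e in estimates], dtype=float)
    return float((r.max() - r.min()) / r.mean())


def z_profile_saturation(
    distances_um: Sequence[float],
    currents_nA: Sequence[float],
    tolerance_pA: float = 5.0,
) -> float:
    """Smallest distance beyond which successive current steps stay below
    ``tolerance_pA`` - the minimum usable bulk distance for z-scans.

    If the profile never settles, the last distance is returned with a
    warning.
    """
    d = np.asarray(distances_um, dtype=float)
    i = np.asarray(currents_nA, dtype=float)
    if d.size != i.size or d.size < 2:
        raise InsufficientDataError("need matching distance/current arrays, >= 2 points")
    if not np.all(np.diff(d) > 0):
        raise DomainError("distances must be strictly increasing")
    steps_pA = np.abs(np.diff(i)) * 1000.0
    below = steps_pA < tolerance_pA
    if not below[-1]:
        warnings.warn(
            "profile never saturates within the scanned range; "
            "returning the last distance",
            stacklevel=2,
        )
        return float(d[-1])
    # last index where a step still exceeds tolerance; settled after it
    exceeding = np.flatnonzero(~below)
    j = 0 if exceeding.size == 0 else exceeding[-1] + 1
    return float(d[j])
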