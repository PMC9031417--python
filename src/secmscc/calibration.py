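"""Calibration curve, somatic-cell-count estimation, mastitis classification
and respiratory-burst quantification.

The measured |dI| grows linearly with somatic cell concentration over the
10^4 - 10^6 cells/mL working range, so calibration is an ordinary
least-squares straight line |dI| = a*N + b fitted to measured calibration
points, inverted for unknown samples as N = (|dI| - b) / a. The fit is
unweighted and keeps its intercept: small systematic offsets (residual
background respiration, electrode positioning) are absorbed by b rather than
forced into the slope.

Classification follows the usual somatic-cell-count bands: below the lower
threshold the quarter is normal, between the thresholds subclinical (latent)
mastitis, at or above the upper threshold clinical mastitis. Defaults are
1e5 / 2e5 cells/mL; regulatory presets for the EU (400,000) and US (750,000)
bulk-milk limits are provided.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import DomainError, ExtrapolationWarning, InsufficientDataError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "MastitisCategory",
    "DiagnosisResult",
    "THRESHOLD_PRESETS",
    "fit_calibration",
    "estimate_cell_count",
    "classify_mastitis",
    "diagnose",
    "burst_ratio",
]

#: (lower, upper) cells/mL classification thresholds by preset name. The
#: "default" bands treat >= 2e5 cells/mL as clinical mastitis; "eu" and "us"
#: substitute the respective regulatory bulk-milk limits as the upper band.
THRESHOLD_PRESETS: Dict[str, Tuple[float, float]] = {
    "default": (1.0e5, 2.0e5),
    "eu": (1.0e5, 4.0e5),
    "us": (1.0e5, 7.5e5),
}


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration measurement: known concentration and measured |dI|."""

    cells_per_ml: float
    mean_abs_delta_i_pA: float
    sd_delta_i_pA: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.cells_per_ml > 0:
            raise DomainError("cells_per_ml must be > 0")
        if self.mean_abs_delta_i_pA < 0:
            raise DomainError("mean_abs_delta_i_pA must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted straight line |dI| = slope * N + intercept.

    ``valid_range_cells_per_ml`` spans the fitted concentrations; estimates
    outside it are extrapolations and are flagged with a warning. A curve
    with non-positive slope is returned (with ``usable = False``) so it can
    be inspected, but it cannot be inverted.
    """

    slope_pA_per_cells_ml: float
    intercept_pA: float
    r_squared: float
    n_points: int
    valid_range_cells_per_ml: Tuple[float, float]

    @property
    def usable(self) -> bool:
        return self.slope_pA_per_cells_ml > 0

    def predict(self, cells_per_ml):
        """Expected |dI| (pA) at a concentration (scalar or array)."""
        return self.slope_pA_per_cells_ml * np.asarray(cells_per_ml) + self.intercept_pA

    def summary(self) -> str:
        lo, hi = self.valid_range_cells_per_ml
        return (
            "SECM-SCC calibration curve\n"
            "--------------------------\n"
            f"slope      {self.slope_pA_per_cells_ml:.4e} pA per cells/mL\n"
            f"intercept  {self.intercept_pA:.3f} pA\n"
            f"R^2        {self.r_squared:.4f}\n"
            f"n points   {self.n_points}\n"
            f"range      {lo:.3g} - {hi:.3g} cells/mL\n"
            f"usable     {self.usable}"
        )

    def plot(self, points: Optional[Sequence[CalibrationPoint]] = None, ax=None):
        """Calibration line (and points, with sd bars) - needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo, hi = self.valid_range_cells_per_ml
        grid = np.linspace(lo, hi, 50)
        ax.plot(grid, self.predict(grid), "k-", lw=1)
        if points:
            n = [p.cells_per_ml for p in points]
            di = [p.mean_abs_delta_i_pA for p in points]
            sd = [p.sd_delta_i_pA or 0.0 for p in points]
            ax.errorbar(n, di, yerr=sd, fmt="o", capsize=3)
        ax.set_xlabel("cell concentration (cells/mL)")
        ax.set_ylabel("|dI| (pA)")
        return ax


class MastitisCategory(str, enum.Enum):
    NORMAL = "normal"
    SUBCLINICAL = "subclinical"
    CLINICAL = "clinical"


@dataclass(frozen=True)
class DiagnosisResult:
    """Estimated somatic cell count and its mastitis band."""

    estimated_cells_per_ml: float
    category: MastitisCategory
    thresholds_cells_per_ml: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.estimated_cells_per_ml < 0:
            raise DomainError("estimated cell count must be >= 0")


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationCurve:
    """Unweighted OLS of |dI| on cell concentration.

    Requires at least two points with distinct concentrations. sd values on
    the points, when present, are carried for reporting but not used as
    weights. A non-positive slope yields a warning and an unusable curve.
    """
    if len(points) < 2 or len({p.cells_per_ml for p in points}) < 2:
        raise InsufficientDataError(
            "calibration needs >= 2 points at distinct concentrations"
        )
    n = np.array([p.cells_per_ml for p in points], dtype=float)
    di = np.array([p.mean_abs_delta_i_pA for p in points], dtype=float)
    res = stats.linregress(n, di)
    if res.slope <= 0:
        warnings.warn(
            f"calibration slope is not positive ({res.slope:.3e} pA per cells/mL); "
            "the curve cannot be inverted",
            stacklevel=2,
        )
    return CalibrationCurve(
        slope_pA_per_cells_ml=float(res.slope),
        intercept_pA=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(points),
        valid_range_cells_per_ml=(float(n.min()), float(n.max())),
    )


def estimate_cell_count(curve: CalibrationCurve, delta_i_pA: float) -> float:
    """Inverse prediction N = (|dI| - intercept) / slope (cells/mL).

    Warns when the estimate falls outside the fitted concentration range
    (the line is linear over roughly 10^4 - 10^6 cells/mL only) and clamps
    negative estimates to zero with a warning.
    """
    if not curve.usable:
        raise DomainError("calibration slope must be > 0 to invert the curve")
    n = (delta_i_pA - curve.intercept_pA) / curve.slope_pA_per_cells_ml
    if n < 0:
        warnings.warn(
            f"|dI| = {delta_i_pA} pA is below the calibration intercept; "
            "clamping the estimate to 0 cells/mL",
            stacklevel=2,
        )
        return 0.0
    lo, hi = curve.valid_range_cells_per_ml
    if not lo <= n <= hi:
        warnings.warn(
            f"estimate {n:.3g} cells/mL lies outside the fitted range "
            f"[{lo:.3g}, {hi:.3g}]; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(n)


def classify_mastitis(
    cells_per_ml: float,
    low_threshold: float = 1.0e5,
    high_threshold: float = 2.0e5,
) -> DiagnosisResult:
    """Band a somatic cell count into normal / subclinical / clinical.

    ``cells < low`` is normal, ``low <= cells < high`` subclinical,
    ``cells >= high`` clinical. Boundaries belong to the higher band.
    """
    if cells_per_ml < 0:
        raise DomainError("cell count must be >= 0")
    if not 0 < low_threshold < high_threshold:
        raise DomainError("thresholds must satisfy 0 < low < high")
    if cells_per_ml < low_threshold:
        cat = MastitisCategory.NORMAL
    elif cells_per_ml < high_threshold:
        cat = MastitisCategory.SUBCLINICAL
    else:
        cat = MastitisCategory.CLINICAL
    return DiagnosisResult(
        estimated_cells_per_ml=float(cells_per_ml),
        category=cat,
        thresholds_cells_per_ml=(low_threshold, high_threshold),
    )


def diagnose(
    curve: CalibrationCurve,
    delta_i_pA: float,
    low_threshold: float = 1.0e5,
    high_threshold: float = 2.0e5,
) -> DiagnosisResult:
    """Estimate the cell count from |dI| and classify it in one step."""
    n = estimate_cell_count(curve, delta_i_pA)
    return classify_mastitis(n, low_threshold, high_threshold)


def burst_ratio(delta_i_stimulated_pA: float, delta_i_control_pA: float) -> float:
    """Respiratory-burst amplification: stimulated |dI| over control |dI|.

    A ratio well above 1 indicates immune cells (monocytes, neutrophils)
    responding to a burst inducer such as PMA with surging oxygen
    consumption.
    """
    if delta_i_control_pA <= 0:
        raise DomainError("control |dI| must be > 0 to form a burst ratio")
    if delta_i_stimulated_pA < 0:
        raise DomainError("stimulated |dI| must be >= 0")
    return delta_i_stimulated_pA / delta_i_control_pA
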