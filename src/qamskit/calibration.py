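"""Linear calibration of detector response against concentration.

Each analyte gets an ordinary least-squares line ``area = slope ×
concentration + intercept`` fitted over a series of standard levels.
From the fit we derive R² (squared Pearson correlation), the residual
standard deviation (n − 2 denominator), the validated linear range
(the span of the supplied levels), and detection/quantification limits
by the 3σ/S and 10σ/S rules with σ the residual standard deviation —
the convention consistent with printed LOQ/LOD ratios of 10/3 in this
assay family.

Weighted (1/x) or quadratic calibration is deliberately out of scope:
the flavonoid responses are linear across the validated ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import (
    QUALIFIER_ABOVE_RANGE,
    QUALIFIER_BELOW_LOQ,
    QUALIFIER_OK,
    QamsError,
)

__all__ = ["CalibrationCurve", "fit_calibration", "lod_loq", "invert_calibration"]


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted per-analyte linear response.

    Units: slope in area per (µg/mL), intercept and residual_sd in area,
    linear range and LOD/LOQ in µg/mL.
    """

    analyte_id: str
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    linear_range: tuple[float, float]
    lod: float
    loq: float
    n_levels: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise QamsError(
                f"calibration for {self.analyte_id!r}: slope must be "
                f"positive, got {self.slope}"
            )
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise QamsError(
                f"calibration for {self.analyte_id!r}: R² out of [0, 1]"
            )
        if self.linear_range[0] >= self.linear_range[1]:
            raise QamsError(
                f"calibration for {self.analyte_id!r}: empty linear range"
            )

    def predict(self, concentration_ug_per_ml: float) -> float:
        """Expected area at a concentration (µg/mL)."""
        return self.slope * concentration_ug_per_ml + self.intercept


def fit_calibration(
    points: Iterable[tuple[float, float]], analyte_id: str
) -> CalibrationCurve:
    """Fit a calibration line to (concentration µg/mL, area) pairs.

    Requires at least three distinct concentration levels.  R² is the
    squared Pearson correlation of area with concentration; the residual
    standard deviation uses the n − 2 denominator of the two-parameter
    fit.  The linear range is the span of the supplied concentrations.

    Raises
    ------
    QamsError
        If fewer than three distinct levels are supplied or the
        concentrations have no variance.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise QamsError(
            f"calibration for {analyte_id!r}: expected (concentration, area) pairs"
        )
    if not np.all(np.isfinite(pts)):
        raise QamsError(f"calibration for {analyte_id!r}: non-finite input")
    conc, area = pts[:, 0], pts[:, 1]
    if len(np.unique(conc)) < 3:
        raise QamsError(
            f"calibration for {analyte_id!r}: need >= 3 distinct "
            f"concentration levels, got {len(np.unique(conc))}"
        )
    if np.ptp(conc) == 0:
        raise QamsError(
            f"calibration for {analyte_id!r}: zero concentration variance"
        )

    fit = stats.linregress(conc, area)
    residuals = area - (fit.slope * conc + fit.intercept)
    n = len(conc)
    residual_sd = float(np.sqrt(np.sum(residuals**2) / (n - 2)))
    r_squared = min(float(fit.rvalue**2), 1.0)
    lod, loq = lod_loq(residual_sd, float(fit.slope))
    return CalibrationCurve(
        analyte_id=analyte_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        residual_sd=residual_sd,
        linear_range=(float(conc.min()), float(conc.max())),
        lod=lod,
        loq=loq,
        n_levels=int(len(np.unique(conc))),
    )


def lod_loq(residual_sd: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits from regression residual noise.

    LOD = 3σ/S and LOQ = 10σ/S with σ the residual standard deviation
    and S the slope, so LOQ/LOD is exactly 10/3.
    """
    if slope <= 0:
        raise QamsError(f"slope must be positive for LOD/LOQ, got {slope}")
    if residual_sd < 0:
        raise QamsError(f"residual SD must be non-negative, got {residual_sd}")
    return 3.0 * residual_sd / slope, 10.0 * residual_sd / slope


def invert_calibration(
    curve: CalibrationCurve, area: float
) -> tuple[float, str]:
    """Convert an area to a concentration (µg/mL) with a qualifier.

    Concentrations below the LOQ are still returned (possibly negative
    for areas below the intercept) but carry the ``below_loq``
    qualifier; concentrations above the fitted range are extrapolated
    and flagged ``above_range`` rather than rejected.
    """
    if not np.isfinite(area):
        raise QamsError(
            f"cannot invert non-finite area {area!r} for {curve.analyte_id!r}"
        )
    concentration = (area - curve.intercept) / curve.slope
    if concentration < curve.loq:
        return concentration, QUALIFIER_BELOW_LOQ
    if concentration > curve.linear_range[1]:
        return concentration, QUALIFIER_ABOVE_RANGE
    return concentration, QUALIFIER_OK


def fit_panel(
    series: dict[str, Sequence[tuple[float, float]]]
) -> dict[str, CalibrationCurve]:
    """Fit calibration curves for a whole analyte panel.

    ``series`` maps analyte id to its (concentration, area) points;
    insertion order is preserved in the returned mapping.
    """
    return {aid: fit_calibration(pts, aid) for aid, pts in series.items()}
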