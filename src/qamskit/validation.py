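"""Method-validation battery: precision, repeatability, stability,
spike recovery.

All dispersion metrics are relative standard deviations,
RSD = 100 × s / mean with the sample (n − 1) standard deviation.
Conventions:

* intraday precision is the RSD of the first day's replicate
  injections; interday precision pools the replicates of all days
  (the stricter of the two common conventions);
* stability is the RSD of re-injections of one solution over a
  24-hour series;
* repeatability is the RSD over independently prepared extracts of the
  same material;
* recovery is the marginal formula
  100 × (measured total − base) / spiked for a sample spiked with a
  known amount of standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibration import CalibrationCurve
from .records import QamsError
from .simulate import StudyBundle

__all__ = [
    "rsd",
    "precision",
    "recovery",
    "stability",
    "ValidationReport",
    "validation_report",
]


def rsd(values: Iterable[float]) -> float:
    """Relative standard deviation in percent (sample SD over mean)."""
    x = np.asarray(list(values), dtype=float)
    if len(x) < 2:
        raise QamsError(f"RSD needs >= 2 values, got {len(x)}")
    mean = x.mean()
    if mean <= 0:
        raise QamsError(f"RSD undefined for non-positive mean {mean}")
    return float(100.0 * x.std(ddof=1) / mean)


def precision(
    replicates_by_day: Mapping[str, Sequence[float]]
) -> tuple[float, float]:
    """(intraday RSD, interday RSD) from replicate areas grouped by day.

    Intraday uses the first day's replicates; interday pools all
    replicates across days.  Needs >= 2 replicates on the first day and
    >= 2 days.
    """
    days = list(replicates_by_day)
    if not days:
        raise QamsError("precision: no days supplied")
    first = list(replicates_by_day[days[0]])
    if len(first) < 2:
        raise QamsError(
            f"precision (intraday arm): day {days[0]!r} has "
            f"{len(first)} replicate(s), need >= 2"
        )
    if len(days) < 2:
        raise QamsError("precision (interday arm): need >= 2 days")
    for day in days:
        if len(replicates_by_day[day]) < 2:
            raise QamsError(
                f"precision (interday arm): day {day!r} has "
                f"{len(replicates_by_day[day])} replicate(s), need >= 2"
            )
    pooled = [v for day in days for v in replicates_by_day[day]]
    return rsd(first), rsd(pooled)


def recovery(
    measured_total: float, base_amount: float, spiked_amount: float
) -> float:
    """Spike recovery: 100 × (measured total − base) / spiked.

    All three amounts in the same unit (mg here); invariant to a common
    unit change.
    """
    if spiked_amount <= 0:
        raise QamsError(
            f"spiked amount must be positive, got {spiked_amount}"
        )
    if base_amount < 0:
        raise QamsError(f"base amount must be non-negative, got {base_amount}")
    return 100.0 * (measured_total - base_amount) / spiked_amount


def stability(timepoint_areas: Iterable[tuple[float, float]]) -> float:
    """RSD of areas over a timepoint series (hours, area)."""
    areas = [a for _, a in timepoint_areas]
    return rsd(areas)


@dataclass(frozen=True)
class ValidationReport:
    """Per-analyte validation metrics, all in percent."""

    analyte_id: str
    intraday_rsd: float
    interday_rsd: float
    repeatability_rsd: float
    stability_rsd: float
    recovery_percent: float | None
    recovery_rsd: float | None


def validation_report(
    bundle: StudyBundle, curves: Mapping[str, CalibrationCurve]
) -> list[ValidationReport]:
    """Compute the validation battery for every analyte of a study.

    Recovery converts each spiked-extract area to a measured total
    amount through the analyte's fitted curve and the spike prep
    (0.50 g portion, study extract volume); analytes with zero native
    content have no recovery set and report missing recovery.
    """
    truth = bundle.truth
    out: list[ValidationReport] = []
    for aid in truth.panel:
        intra, inter = precision(bundle.precision_areas[aid])
        stab = stability(bundle.stability_areas[aid])
        repeat = rsd(bundle.repeatability_areas[aid])

        rec_mean: float | None = None
        rec_rsd: float | None = None
        rset = bundle.recovery_sets.get(aid)
        if rset is not None:
            curve = curves[aid]
            recoveries = []
            for area in rset.areas:
                conc = (area - curve.intercept) / curve.slope
                measured_total_mg = conc * truth.prep_volume_ml / 1000.0
                recoveries.append(
                    recovery(
                        measured_total_mg,
                        rset.base_amount_mg,
                        rset.spiked_amount_mg,
                    )
                )
            rec_mean = float(np.mean(recoveries))
            rec_rsd = rsd(recoveries) if len(recoveries) > 1 else None
        out.append(
            ValidationReport(
                analyte_id=aid,
                intraday_rsd=intra,
                interday_rsd=inter,
                repeatability_rsd=repeat,
                stability_rsd=stab,
                recovery_percent=rec_mean,
                recovery_rsd=rec_rsd,
            )
        )
    return out
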