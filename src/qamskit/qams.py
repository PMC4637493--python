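"""Single-marker quantification (QAMS) via relative correction factors.

The method quantifies a panel of analytes from a single reference
standard.  For marker *k* and analyte *m*, the relative correction
factor is the ratio of concentration-normalised detector responses

    f = (W_k × A_m) / (W_m × A_k),

estimated on mixed-standard runs where both concentrations are known,
averaged over acquisition conditions (injection volumes here), and then
frozen.  On a sample run only the marker needs a calibration curve: its
area gives W_k, and the analyte concentration follows from the unique
rearrangement

    W_m = (W_k × A_m) / (f × A_k).

f is dimensionless and invariant to any common rescaling of the two
areas (detector gain) or of the two concentrations, which is what makes
it transferable across instruments and columns.  The method is exact
when detector response is proportional to concentration; a non-zero
calibration intercept introduces a small concentration-dependent bias
(see the methods note).

Accuracy of the single-marker result is reported as
100 × W_qams / W_es against the external-standard content for the same
cell, to four significant figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibration import CalibrationCurve, invert_calibration
from .records import (
    QUALIFIER_BELOW_LOQ,
    InjectionRecord,
    QamsError,
    QuantResult,
    SamplePrep,
)
from .quantify import mean_areas_by_cell
from .simulate import REFERENCE_VOLUME_UL

__all__ = [
    "RCFEstimate",
    "AccuracyRecord",
    "RobustnessResult",
    "compute_rcf",
    "rcf_summary",
    "rcf_robustness",
    "qams_quantify",
    "accuracy",
    "rcf_from_standards",
    "qams_batch",
    "accuracy_table",
    "round_sig",
]


def round_sig(x: float, digits: int = 4) -> float:
    """Round to a number of significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class RCFEstimate:
    """A relative correction factor summarised over conditions.

    ``per_condition_values`` keeps (condition label, f) in input order;
    ``mean_f`` is their arithmetic mean and ``rsd_percent`` the sample
    (n − 1) relative standard deviation in percent.
    """

    analyte_id: str
    marker_id: str
    per_condition_values: tuple[tuple[str, float], ...]
    mean_f: float
    rsd_percent: float

    def __post_init__(self) -> None:
        if any(f <= 0 for _, f in self.per_condition_values):
            raise QamsError(
                f"RCF for {self.analyte_id!r}: non-positive f value"
            )


@dataclass(frozen=True)
class AccuracyRecord:
    """Single-marker vs external-standard content for one cell."""

    sample_id: str
    analyte_id: str
    w_qams_mg_per_g: float
    w_es_mg_per_g: float
    accuracy_percent: float


@dataclass(frozen=True)
class RobustnessResult:
    """f per (instrument, column) group with the maximal relative spread."""

    analyte_id: str
    per_group: tuple[tuple[tuple[str, str], float], ...]
    spread_percent: float


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not (value > 0) or not math.isfinite(value):
            raise QamsError(f"{name} must be positive and finite, got {value}")


def compute_rcf(w_k: float, a_k: float, w_m: float, a_m: float) -> float:
    """Relative correction factor f = (W_k × A_m) / (W_m × A_k).

    W_k, A_k are the marker's concentration (µg/mL) and area; W_m, A_m
    the analyte's.  All inputs must be positive.
    """
    _require_positive(W_k=w_k, A_k=a_k, W_m=w_m, A_m=a_m)
    return (w_k * a_m) / (w_m * a_k)


def rcf_summary(
    values: Sequence[tuple[str, float]],
    *,
    analyte_id: str = "",
    marker_id: str = "",
) -> RCFEstimate:
    """Summarise per-condition f values into mean and RSD%.

    Mean is arithmetic; RSD uses the sample (n − 1) standard deviation.
    At least two values are required.
    """
    vals = [(str(c), float(f)) for c, f in values]
    if len(vals) < 2:
        raise QamsError(
            f"RCF summary for {analyte_id or 'analyte'}: need >= 2 values, "
            f"got {len(vals)}"
        )
    f = np.array([v for _, v in vals])
    mean = float(f.mean())
    rsd = float(100.0 * f.std(ddof=1) / mean)
    return RCFEstimate(
        analyte_id=analyte_id,
        marker_id=marker_id,
        per_condition_values=tuple(vals),
        mean_f=mean,
        rsd_percent=rsd,
    )


def rcf_robustness(
    groups: Mapping[tuple[str, str], float], *, analyte_id: str = ""
) -> RobustnessResult:
    """Spread of f across instrument × column groups:
    100 × (max − min) / mean."""
    items = [((str(i), str(c)), float(f)) for (i, c), f in groups.items()]
    if len(items) < 2:
        raise QamsError(
            f"RCF robustness for {analyte_id or 'analyte'}: need >= 2 groups"
        )
    f = np.array([v for _, v in items])
    if np.any(f <= 0):
        raise QamsError(f"RCF robustness for {analyte_id!r}: non-positive f")
    spread = float(100.0 * (f.max() - f.min()) / f.mean())
    return RobustnessResult(
        analyte_id=analyte_id, per_group=tuple(items), spread_percent=spread
    )


def qams_quantify(
    f: float,
    a_m: float,
    w_k: float,
    a_k: float,
    prep: SamplePrep,
    *,
    sample_id: str = "",
    analyte_id: str = "",
) -> QuantResult:
    """Quantify one analyte from the marker's run context.

    W_m = (W_k × A_m) / (f × A_k), converted to mg/g through the prep
    arithmetic.  ``w_k`` is the marker concentration obtained from the
    marker's own calibration curve on the same run; ``a_k`` and ``a_m``
    are the marker and analyte areas of that run.
    """
    _require_positive(f=f, A_m=a_m, W_k=w_k, A_k=a_k)
    w_m = (w_k * a_m) / (f * a_k)
    return QuantResult(
        sample_id=sample_id,
        analyte_id=analyte_id,
        method="qams",
        content_mg_per_g=prep.content_mg_per_g(w_m),
        concentration_ug_per_ml=w_m,
    )


def accuracy(w_qams: float, w_es: float) -> float:
    """Single-marker accuracy: 100 × w_qams / w_es, to 4 significant
    figures (the reporting precision of the content tables)."""
    _require_positive(w_qams=w_qams, w_es=w_es)
    return round_sig(100.0 * w_qams / w_es, 4)


# ---------------------------------------------------------------------------
# batch pathways over injection records
# ---------------------------------------------------------------------------

def rcf_from_standards(
    standard_runs: Iterable[InjectionRecord],
    standard_concentrations: Mapping[str, float],
    marker_id: str,
    *,
    analytes: Sequence[str] | None = None,
) -> dict[str, RCFEstimate]:
    """Estimate per-analyte RCFs from mixed-standard runs across
    injection volumes.

    Replicate areas are averaged per (volume, analyte) first; f is then
    computed at each volume from marker and analyte areas of the same
    volume (never across volumes) and summarised over volumes.  Only
    runs from a single instrument × column group should be passed here;
    use :func:`rcf_robustness` to compare groups.
    """
    runs = list(standard_runs)
    if not any(r.analyte_id == marker_id for r in runs):
        raise QamsError(f"marker {marker_id!r} missing from standard runs")

    # mean raw area per (volume, analyte) — no volume normalisation:
    # marker and analyte share the volume, so the factor cancels in f
    sums: dict[tuple[float, str], list[float]] = {}
    volumes: list[float] = []
    for rec in runs:
        if rec.injection_volume_ul not in volumes:
            volumes.append(rec.injection_volume_ul)
        sums.setdefault((rec.injection_volume_ul, rec.analyte_id), []).append(
            rec.area
        )
    means = {key: sum(v) / len(v) for key, v in sums.items()}

    if analytes is None:
        analytes = []
        for rec in runs:
            if rec.analyte_id != marker_id and rec.analyte_id not in analytes:
                analytes.append(rec.analyte_id)

    w_k = standard_concentrations[marker_id]
    out: dict[str, RCFEstimate] = {}
    for aid in analytes:
        if aid == marker_id:
            continue
        w_m = standard_concentrations[aid]
        values: list[tuple[str, float]] = []
        for volume in sorted(volumes):
            a_k = means.get((volume, marker_id))
            a_m = means.get((volume, aid))
            if a_k is None or a_m is None:
                continue
            values.append(
                (f"{volume:g} uL", compute_rcf(w_k, a_k, w_m, a_m))
            )
        out[aid] = rcf_summary(values, analyte_id=aid, marker_id=marker_id)
    return out


def qams_batch(
    sample_runs: Sequence[InjectionRecord],
    rcfs: Mapping[str, RCFEstimate],
    marker_curve: CalibrationCurve,
    prep: SamplePrep,
    *,
    reference_volume_ul: float = REFERENCE_VOLUME_UL,
) -> list[QuantResult]:
    """Single-marker quantification of a batch of sample runs.

    Per sample: the marker's mean area is inverted through its own
    calibration curve to give W_k, and every analyte with an RCF is
    quantified through ``W_m = W_k·A_m/(f·A_k)``.  Samples whose marker
    falls below its LOQ yield below-LOQ results for every analyte (the
    marker anchor is unusable).
    """
    marker_id = marker_curve.analyte_id
    means = mean_areas_by_cell(sample_runs, reference_volume_ul=reference_volume_ul)
    samples: list[str] = []
    for rec in sample_runs:
        if rec.sample_id not in samples:
            samples.append(rec.sample_id)

    results: list[QuantResult] = []
    for sample in samples:
        a_k = means.get((sample, marker_id))
        if a_k is None:
            raise QamsError(
                f"sample {sample!r}: marker {marker_id!r} not present in runs"
            )
        w_k, qualifier = invert_calibration(marker_curve, a_k)
        for aid, est in rcfs.items():
            a_m = means.get((sample, aid))
            if (
                a_m is None
                or a_m <= 0
                or qualifier == QUALIFIER_BELOW_LOQ
                or w_k <= 0
            ):
                results.append(
                    QuantResult(
                        sample_id=sample,
                        analyte_id=aid,
                        method="qams",
                        content_mg_per_g=None,
                        qualifier=QUALIFIER_BELOW_LOQ,
                    )
                )
                continue
            results.append(
                qams_quantify(
                    est.mean_f,
                    a_m,
                    w_k,
                    a_k,
                    prep,
                    sample_id=sample,
                    analyte_id=aid,
                )
            )
    return results


def accuracy_table(
    es_results: Iterable[QuantResult], qams_results: Iterable[QuantResult]
) -> list[AccuracyRecord]:
    """Join the two methods per (sample, analyte) and compute accuracy.

    Cells missing (below LOQ) in either method are skipped, not imputed.
    """
    es = {
        (r.sample_id, r.analyte_id): r.content_mg_per_g
        for r in es_results
        if r.content_mg_per_g is not None
    }
    out: list[AccuracyRecord] = []
    for r in qams_results:
        if r.content_mg_per_g is None:
            continue
        w_es = es.get((r.sample_id, r.analyte_id))
        if w_es is None or w_es <= 0:
            continue
        out.append(
            AccuracyRecord(
                sample_id=r.sample_id,
                analyte_id=r.analyte_id,
                w_qams_mg_per_g=r.content_mg_per_g,
                w_es_mg_per_g=w_es,
                accuracy_percent=accuracy(r.content_mg_per_g, w_es),
            )
        )
    return out
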