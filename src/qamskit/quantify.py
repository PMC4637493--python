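"""External-standard quantification: area → concentration → content.

Each analyte is quantified against its own calibration curve; replicate
injections of a sample are averaged on the area scale before inversion,
and areas acquired at a non-reference injection volume are rescaled to
the reference volume first (response is linear in volume on a fixed
method).  Contents are reported in mg per g of powdered material via
the extraction arithmetic of :class:`~qamskit.records.SamplePrep`.
Measurements below the limit of quantification yield a missing content
with the ``below_loq`` qualifier rather than a zero.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .calibration import CalibrationCurve, invert_calibration
from .records import (
    QUALIFIER_BELOW_LOQ,
    InjectionRecord,
    QamsError,
    QuantResult,
    SamplePrep,
)
from .simulate import REFERENCE_VOLUME_UL

__all__ = ["content_from_area", "quantify_batch"]


def content_from_area(
    area: float,
    curve: CalibrationCurve,
    prep: SamplePrep,
    *,
    sample_id: str = "",
    analyte_id: str | None = None,
) -> QuantResult:
    """Convert one (volume-normalised) area to a content in mg/g.

    ``analyte_id``, when given, must match the curve's analyte; this
    guards against pairing a peak with the wrong calibration.
    """
    if analyte_id is not None and analyte_id != curve.analyte_id:
        raise QamsError(
            f"area for analyte {analyte_id!r} paired with calibration "
            f"for {curve.analyte_id!r}"
        )
    concentration, qualifier = invert_calibration(curve, area)
    if qualifier == QUALIFIER_BELOW_LOQ:
        return QuantResult(
            sample_id=sample_id,
            analyte_id=curve.analyte_id,
            method="external_standard",
            content_mg_per_g=None,
            qualifier=qualifier,
            concentration_ug_per_ml=concentration,
        )
    return QuantResult(
        sample_id=sample_id,
        analyte_id=curve.analyte_id,
        method="external_standard",
        content_mg_per_g=prep.content_mg_per_g(concentration),
        qualifier=qualifier,
        concentration_ug_per_ml=concentration,
    )


def mean_areas_by_cell(
    records: Iterable[InjectionRecord],
    *,
    reference_volume_ul: float = REFERENCE_VOLUME_UL,
) -> dict[tuple[str, str], float]:
    """Average replicate areas per (sample, analyte), normalised to the
    reference injection volume.  Insertion order of first appearance is
    preserved (dicts are ordered)."""
    sums: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        key = (rec.sample_id, rec.analyte_id)
        scaled = rec.area * reference_volume_ul / rec.injection_volume_ul
        sums.setdefault(key, []).append(scaled)
    return {key: sum(v) / len(v) for key, v in sums.items()}


def quantify_batch(
    records: Sequence[InjectionRecord],
    curves: Mapping[str, CalibrationCurve],
    prep: SamplePrep,
    *,
    panel: Sequence[str] | None = None,
    reference_volume_ul: float = REFERENCE_VOLUME_UL,
) -> list[QuantResult]:
    """Quantify every (sample, analyte) cell of a batch of injections.

    Produces exactly one :class:`QuantResult` per sample × panel
    analyte, ordered by first appearance of the sample and then panel
    order.  Every analyte present in the records must have a curve.
    """
    present = []
    for rec in records:
        if rec.analyte_id not in present:
            present.append(rec.analyte_id)
    missing = [aid for aid in present if aid not in curves]
    if missing:
        raise QamsError(
            "no calibration curve for analyte(s): " + ", ".join(sorted(missing))
        )
    if panel is None:
        panel = present
    else:
        missing = [aid for aid in panel if aid not in curves]
        if missing:
            raise QamsError(
                "no calibration curve for analyte(s): " + ", ".join(sorted(missing))
            )

    means = mean_areas_by_cell(records, reference_volume_ul=reference_volume_ul)
    samples: list[str] = []
    for rec in records:
        if rec.sample_id not in samples:
            samples.append(rec.sample_id)

    results: list[QuantResult] = []
    for sample in samples:
        for aid in panel:
            key = (sample, aid)
            if key not in means:
                results.append(
                    QuantResult(
                        sample_id=sample,
                        analyte_id=aid,
                        method="external_standard",
                        content_mg_per_g=None,
                        qualifier=QUALIFIER_BELOW_LOQ,
                    )
                )
                continue
            results.append(
                content_from_area(
                    means[key], curves[aid], prep, sample_id=sample, analyte_id=aid
                )
            )
    return results
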