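"""Core record types shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field


class QamsError(ValueError):
    """Base class for domain errors raised by qamskit."""


@dataclass(frozen=True)
class InjectionRecord:
    """One integrated peak from one chromatographic run.

    Areas are in detector units; the injection volume provides the
    scaling context needed to compare runs acquired at different
    volumes (areas scale linearly with volume on a fixed method).
    """

    run_id: str
    sample_id: str
    instrument_id: str
    column_id: str
    injection_volume_ul: float
    analyte_id: str
    retention_time_min: float
    area: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.injection_volume_ul <= 0:
            raise QamsError(
                f"run {self.run_id!r}: injection volume must be positive, "
                f"got {self.injection_volume_ul}"
            )


@dataclass(frozen=True)
class SamplePrep:
    """Extraction arithmetic: grams of powdered seed brought to a final
    extract volume in mL.  Converts extract concentration (µg/mL) to
    content (mg/g): content = concentration × volume / (mass × 1000).
    """

    mass_g: float = 0.1
    final_volume_ml: float = 10.0

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise QamsError(f"prep mass must be positive, got {self.mass_g} g")
        if self.final_volume_ml <= 0:
            raise QamsError(
                f"prep volume must be positive, got {self.final_volume_ml} mL"
            )

    def content_mg_per_g(self, concentration_ug_per_ml: float) -> float:
        return concentration_ug_per_ml * self.final_volume_ml / (self.mass_g * 1000.0)


#: Result qualifiers: below the limit of quantification, or extrapolated
#: above the fitted calibration range.
QUALIFIER_OK = "ok"
QUALIFIER_BELOW_LOQ = "below_loq"
QUALIFIER_ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class QuantResult:
    """Per-sample, per-analyte content with the method that produced it.

    ``content_mg_per_g`` is None when the measurement fell below the
    limit of quantification (rendered as an em dash in wide reports).
    """

    sample_id: str
    analyte_id: str
    method: str                      # "external_standard" | "qams"
    content_mg_per_g: float | None
    qualifier: str = QUALIFIER_OK
    concentration_ug_per_ml: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.method not in ("external_standard", "qams"):
            raise QamsError(f"unknown quantification method {self.method!r}")
        if self.content_mg_per_g is not None and self.content_mg_per_g < 0:
            raise QamsError(
                f"{self.sample_id}/{self.analyte_id}: negative content "
                f"{self.content_mg_per_g}"
            )
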