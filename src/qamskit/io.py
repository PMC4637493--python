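"""CSV readers/writers and study configuration.

Peak tables are tidy CSVs, one row per detected peak; calibration
series are (analyte, concentration, area) CSVs.  Wide content reports
render missing cells as an em dash, tidy exports leave them empty.
Report rounding mirrors common analytical reporting: contents to four
significant figures, correction factors to three, RSDs to two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import refdata
from .calibration import CalibrationCurve
from .qams import AccuracyRecord, RCFEstimate, RobustnessResult, round_sig
from .records import InjectionRecord, QamsError, QuantResult
from .validation import ValidationReport

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "StudyConfig",
    "read_peak_table",
    "write_peak_table",
    "read_calibration_series",
    "write_calibration_series",
    "write_chromatogram",
    "calibration_report_frame",
    "validation_report_frame",
    "rcf_volume_frame",
    "rcf_robustness_frame",
    "contents_wide_frame",
    "accuracy_frame",
]

PEAK_TABLE_COLUMNS = (
    "run_id",
    "sample_id",
    "instrument_id",
    "column_id",
    "injection_volume_ul",
    "analyte_id",
    "retention_time_min",
    "area",
)

MISSING_CELL = "—"


@dataclass(frozen=True)
class StudyConfig:
    """Declarative description of one study run."""

    panel: tuple[str, ...] = refdata.PANEL
    marker_id: str = refdata.MARKER_ID
    qams_exclusions: tuple[str, ...] = refdata.QAMS_EXCLUDED
    prep_mass_g: float = 0.1
    prep_volume_ml: float = 10.0
    injection_volumes_ul: tuple[float, ...] = refdata.RCF_VOLUMES_UL
    noise_cv: float = 0.02
    seed: int = 0
    instruments: tuple[tuple[str, str], ...] = (
        ("instrument-A", "column-1"),
        ("instrument-A", "column-2"),
        ("instrument-B", "column-1"),
        ("instrument-B", "column-2"),
    )
    retention_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    outdir: str = "qams-report"

    def __post_init__(self) -> None:
        if self.marker_id not in self.panel:
            raise QamsError(
                f"marker {self.marker_id!r} is not in the analyte panel"
            )
        unknown = [a for a in self.qams_exclusions if a not in self.panel]
        if unknown:
            raise QamsError(f"exclusions outside the panel: {unknown}")
        if any(v <= 0 for v in self.injection_volumes_ul):
            raise QamsError("injection volumes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in (
            "marker_id", "prep_mass_g", "prep_volume_ml", "noise_cv",
            "seed", "outdir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "panel" in raw:
            kwargs["panel"] = tuple(raw["panel"])
        if "qams_exclusions" in raw:
            kwargs["qams_exclusions"] = tuple(raw["qams_exclusions"])
        if "injection_volumes_ul" in raw:
            kwargs["injection_volumes_ul"] = tuple(raw["injection_volumes_ul"])
        if "instruments" in raw:
            kwargs["instruments"] = tuple(
                (str(i), str(c)) for i, c in raw["instruments"]
            )
        if "marker_id" in kwargs:
            kwargs["marker_id"] = refdata.resolve_analyte(kwargs["marker_id"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["retention_windows"] = {
            k: list(v) for k, v in self.retention_windows.items()
        }
        return d


# ---------------------------------------------------------------------------
# peak tables & calibration series
# ---------------------------------------------------------------------------

def write_peak_table(records: Iterable[InjectionRecord], path: str | Path) -> None:
    rows = [
        {col: getattr(r, col) for col in PEAK_TABLE_COLUMNS} for r in records
    ]
    # %.17g preserves doubles exactly across the write/read round trip
    pd.DataFrame(rows, columns=list(PEAK_TABLE_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_peak_table(
    path: str | Path, *, panel: Sequence[str] | None = None
) -> list[InjectionRecord]:
    """Read and validate a peak-table CSV.

    Rejects unknown analyte ids (when a panel is given), duplicate
    (run, analyte) rows, and malformed numeric fields — errors carry
    1-based file line numbers (header is line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise QamsError(f"{path}: missing peak-table columns {missing}")

    records: list[InjectionRecord] = []
    seen: dict[tuple[str, str], int] = {}
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            volume = float(row["injection_volume_ul"])
            rt = float(row["retention_time_min"])
            area = float(row["area"])
        except ValueError:
            errors.append(f"line {line}: non-numeric field")
            continue
        aid = row["analyte_id"]
        if panel is not None and aid not in panel:
            errors.append(f"line {line}: unknown analyte {aid!r}")
            continue
        key = (row["run_id"], aid)
        if key in seen:
            errors.append(
                f"line {line}: duplicate (run, analyte) {key!r} "
                f"(first at line {seen[key]})"
            )
            continue
        seen[key] = line
        records.append(
            InjectionRecord(
                run_id=row["run_id"],
                sample_id=row["sample_id"],
                instrument_id=row["instrument_id"],
                column_id=row["column_id"],
                injection_volume_ul=volume,
                analyte_id=aid,
                retention_time_min=rt,
                area=area,
            )
        )
    if errors:
        raise QamsError(f"{path}: " + "; ".join(errors))
    return records


def write_calibration_series(
    series: Mapping[str, Sequence[tuple[float, float]]], path: str | Path
) -> None:
    rows = [
        {"analyte_id": aid, "concentration_ug_per_ml": c, "area": a}
        for aid, pts in series.items()
        for c, a in pts
    ]
    pd.DataFrame(
        rows, columns=["analyte_id", "concentration_ug_per_ml", "area"]
    ).to_csv(path, index=False, float_format="%.17g")


def read_calibration_series(
    path: str | Path,
) -> dict[str, list[tuple[float, float]]]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("analyte_id", "concentration_ug_per_ml", "area"):
        if col not in df.columns:
            raise QamsError(f"{path}: missing calibration column {col!r}")
    out: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["analyte_id"]), []).append(
            (float(row["concentration_ug_per_ml"]), float(row["area"]))
        )
    return out


def write_chromatogram(chrom, path: str | Path) -> None:
    pd.DataFrame(
        {"time_min": chrom.time_min, "signal": chrom.signal}
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# report frames
# ---------------------------------------------------------------------------

def calibration_report_frame(
    curves: Mapping[str, CalibrationCurve]
) -> pd.DataFrame:
    rows = []
    for aid, c in curves.items():
        rows.append(
            {
                "analyte_id": aid,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": round(c.r_squared, 4),
                "range_low_ug_per_ml": c.linear_range[0],
                "range_high_ug_per_ml": c.linear_range[1],
                "lod_ug_per_ml": round_sig(c.lod, 4),
                "loq_ug_per_ml": round_sig(c.loq, 4),
                "n_levels": c.n_levels,
            }
        )
    return pd.DataFrame(rows)


def validation_report_frame(reports: Sequence[ValidationReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "analyte_id": r.analyte_id,
                "intraday_rsd_percent": round_sig(r.intraday_rsd, 2),
                "interday_rsd_percent": round_sig(r.interday_rsd, 2),
                "repeatability_rsd_percent": round_sig(r.repeatability_rsd, 2),
                "stability_rsd_percent": round_sig(r.stability_rsd, 2),
                "recovery_percent": (
                    round_sig(r.recovery_percent, 4)
                    if r.recovery_percent is not None
                    else None
                ),
                "recovery_rsd_percent": (
                    round_sig(r.recovery_rsd, 2)
                    if r.recovery_rsd is not None
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)


def rcf_volume_frame(rcfs: Mapping[str, RCFEstimate]) -> pd.DataFrame:
    """Wide per-volume f table with Mean and RSD% summary rows."""
    conditions: list[str] = []
    for est in rcfs.values():
        for cond, _ in est.per_condition_values:
            if cond not in conditions:
                conditions.append(cond)
    rows = []
    for cond in conditions:
        row: dict = {"condition": cond}
        for aid, est in rcfs.items():
            vals = dict(est.per_condition_values)
            row[aid] = round_sig(vals[cond], 3) if cond in vals else None
        rows.append(row)
    rows.append(
        {"condition": "Mean"}
        | {aid: round_sig(est.mean_f, 3) for aid, est in rcfs.items()}
    )
    rows.append(
        {"condition": "RSD%"}
        | {aid: round_sig(est.rsd_percent, 2) for aid, est in rcfs.items()}
    )
    return pd.DataFrame(rows)


def rcf_robustness_frame(
    results: Mapping[str, RobustnessResult]
) -> pd.DataFrame:
    groups: list[tuple[str, str]] = []
    for res in results.values():
        for g, _ in res.per_group:
            if g not in groups:
                groups.append(g)
    rows = []
    for g in groups:
        row: dict = {"instrument_id": g[0], "column_id": g[1]}
        for aid, res in results.items():
            vals = dict(res.per_group)
            row[aid] = round_sig(vals[g], 3) if g in vals else None
        rows.append(row)
    rows.append(
        {"instrument_id": "spread%", "column_id": ""}
        | {aid: round_sig(res.spread_percent, 3) for aid, res in results.items()}
    )
    return pd.DataFrame(rows)


def contents_wide_frame(
    results: Iterable[QuantResult], *, panel: Sequence[str] | None = None
) -> pd.DataFrame:
    """Samples × analytes content table (mg/g), missing cells as an
    em dash, contents rounded to 4 significant figures."""
    results = list(results)
    if panel is None:
        panel = []
        for r in results:
            if r.analyte_id not in panel:
                panel.append(r.analyte_id)
    samples: list[str] = []
    for r in results:
        if r.sample_id not in samples:
            samples.append(r.sample_id)
    cells = {
        (r.sample_id, r.analyte_id): r.content_mg_per_g for r in results
    }
    rows = []
    for s in samples:
        row: dict = {"sample_id": s}
        for aid in panel:
            v = cells.get((s, aid))
            row[aid] = MISSING_CELL if v is None else round_sig(v, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def accuracy_frame(records: Sequence[AccuracyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "analyte_id": r.analyte_id,
                "qams_mg_per_g": round_sig(r.w_qams_mg_per_g, 4),
                "external_standard_mg_per_g": round_sig(r.w_es_mg_per_g, 4),
                "accuracy_percent": round_sig(r.accuracy_percent, 4),
            }
            for r in records
        ]
    )
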