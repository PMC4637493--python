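"""End-to-end orchestration: simulate (or load) a study, fit
calibrations, run the validation battery, estimate correction factors,
quantify by both methods, and compare.

Outputs, written under the configured directory, mirror the report
shapes of a single-marker study: a calibration report, a validation
report, per-volume and per-instrument correction-factor tables, wide
content tables for both methods, the accuracy comparison, and a JSON
provenance record (config, seed, package version, config hash).  All
outputs are deterministic given seed and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as qio
from . import refdata
from .calibration import CalibrationCurve, fit_panel
from .qams import (
    AccuracyRecord,
    RCFEstimate,
    RobustnessResult,
    accuracy_table,
    qams_batch,
    rcf_from_standards,
    rcf_robustness,
)
from .records import QamsError, QuantResult, SamplePrep
from .quantify import quantify_batch
from .simulate import StudyBundle, StudyTruth, default_study_truth, generate_study
from .validation import ValidationReport, validation_report

logger = logging.getLogger("qamskit")

__all__ = ["PipelineResult", "run_pipeline", "truth_from_config"]


@dataclass(frozen=True)
class PipelineResult:
    """Everything one pipeline run produced, pre- and post-rounding."""

    config: qio.StudyConfig
    bundle: StudyBundle
    curves: Mapping[str, CalibrationCurve]
    validation: list[ValidationReport]
    rcfs: Mapping[str, RCFEstimate]
    robustness: Mapping[str, RobustnessResult]
    es_results: list[QuantResult]
    qams_results: list[QuantResult]
    accuracy: list[AccuracyRecord]
    frames: Mapping[str, pd.DataFrame]


def truth_from_config(config: qio.StudyConfig) -> StudyTruth:
    """Build the simulation truth a config describes (default panel
    contents and detector parameters, config-controlled noise/seed)."""
    base = default_study_truth(seed=config.seed, noise_cv=config.noise_cv)
    return StudyTruth(
        contents=base.contents,
        calibration=base.calibration,
        calibration_ranges=base.calibration_ranges,
        noise_cv=config.noise_cv,
        prep_mass_g=config.prep_mass_g,
        prep_volume_ml=config.prep_volume_ml,
        injection_volumes_ul=config.injection_volumes_ul,
        marker_id=config.marker_id,
        instruments=config.instruments,
        seed=config.seed,
    )


def _config_hash(config: qio.StudyConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: qio.StudyConfig,
    *,
    bundle: StudyBundle | None = None,
    outdir: str | Path | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run the full study workflow.

    With no ``bundle`` a synthetic study is generated from the config.
    Stage failures abort with the stage name and offending input in the
    message.
    """
    if bundle is None:
        bundle = generate_study(truth_from_config(config))
    prep = SamplePrep(config.prep_mass_g, config.prep_volume_ml)
    marker = config.marker_id

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    name = stage("calibration")
    try:
        curves = fit_panel(bundle.calibration_series)
    except QamsError as err:
        raise QamsError(f"stage {name!r} failed: {err}") from err

    name = stage("validation")
    try:
        reports = validation_report(bundle, curves)
    except QamsError as err:
        raise QamsError(f"stage {name!r} failed: {err}") from err

    name = stage("rcf")
    qams_panel = [
        aid
        for aid in config.panel
        if aid != marker and aid not in config.qams_exclusions
    ]
    primary = bundle.truth.instruments[0]
    primary_runs = [
        r
        for r in bundle.standard_runs
        if (r.instrument_id, r.column_id) == primary
    ]
    try:
        rcfs = rcf_from_standards(
            primary_runs,
            bundle.standard_concentrations,
            marker,
            analytes=qams_panel,
        )
    except QamsError as err:
        raise QamsError(f"stage {name!r} failed: {err}") from err

    name = stage("rcf_robustness")
    try:
        per_group_f: dict[str, dict[tuple[str, str], float]] = {
            aid: {} for aid in qams_panel
        }
        for group in {
            (r.instrument_id, r.column_id) for r in bundle.standard_runs
        }:
            runs = [
                r
                for r in bundle.standard_runs
                if (r.instrument_id, r.column_id) == group
                and r.injection_volume_ul == bundle.truth.reference_volume_ul
            ]
            if not runs:
                continue
            sums: dict[str, list[float]] = {}
            for r in runs:
                sums.setdefault(r.analyte_id, []).append(r.area)
            means = {aid: sum(v) / len(v) for aid, v in sums.items()}
            w_k = bundle.standard_concentrations[marker]
            for aid in qams_panel:
                per_group_f[aid][group] = (
                    w_k * means[aid]
                ) / (bundle.standard_concentrations[aid] * means[marker])
        robustness = {
            aid: rcf_robustness(groups, analyte_id=aid)
            for aid, groups in per_group_f.items()
        }
    except QamsError as err:
        raise QamsError(f"stage {name!r} failed: {err}") from err

    name = stage("external_standard_quantification")
    try:
        es_results = quantify_batch(
            bundle.sample_runs, curves, prep, panel=config.panel
        )
    except QamsError as err:
        raise QamsError(f"stage {name!r} failed: {err}") from err

    name = stage("qams_quantification")
    try:
        qams_results = qams_batch(
            bundle.sample_runs, rcfs, curves[marker], prep
        )
    except QamsError as err:
        raise QamsError(f"stage {name!r} failed: {err}") from err

    name = stage("accuracy")
    try:
        acc = accuracy_table(es_results, qams_results)
    except QamsError as err:
        raise QamsError(f"stage {name!r} failed: {err}") from err

    frames = {
        "calibration_report": qio.calibration_report_frame(curves),
        "validation_report": qio.validation_report_frame(reports),
        "rcf_by_volume": qio.rcf_volume_frame(rcfs),
        "rcf_by_instrument": qio.rcf_robustness_frame(robustness),
        "contents_external_standard": qio.contents_wide_frame(
            es_results, panel=config.panel
        ),
        "contents_qams": qio.contents_wide_frame(qams_results, panel=qams_panel),
        "qams_accuracy": qio.accuracy_frame(acc),
    }

    if write:
        out = Path(outdir if outdir is not None else config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for fname, frame in frames.items():
            frame.to_csv(out / f"{fname}.csv", index=False)
        provenance = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "package": "qamskit",
            "version": _package_version(),
            "n_standard_runs": len(bundle.standard_runs),
            "n_sample_runs": len(bundle.sample_runs),
            "warnings": list(bundle.warnings),
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n"
        )
        logger.info("report written to %s", out)

    return PipelineResult(
        config=config,
        bundle=bundle,
        curves=curves,
        validation=reports,
        rcfs=rcfs,
        robustness=robustness,
        es_results=es_results,
        qams_results=qams_results,
        accuracy=acc,
        frames=frames,
    )


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("qamskit")
    except PackageNotFoundError:
        return "unknown"
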