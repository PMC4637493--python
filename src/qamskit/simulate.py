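"""Synthetic HPLC-DAD studies: chromatograms, peak tables, calibration
series, multi-volume standard runs, and validation replicate sets.

The generator stands in for the instrument.  Two layers are provided:

* a signal-level simulator (:func:`simulate_chromatogram`,
  :func:`integrate_peaks`, :func:`snr`) producing Gaussian peaks on a
  drifting baseline with white detector noise — enough structure to
  exercise peak integration without modelling tailing or spectra;
* a study-level generator (:func:`generate_study`) that emits the peak
  tables and calibration series the analysis pipeline consumes, using
  the published calibration parameters as detector truth and published
  batch contents as sample composition.

Statistical model of the study layer: the expected area of analyte *i*
at extract concentration *c* (µg/mL) and injection volume *v* (µL) is
``(slope_i · c + intercept_i) · v / v_ref`` with v_ref = 10 µL, and the
observed area is the expectation times a mean-one lognormal factor with
a stated coefficient of variation (multiplicative noise matches the
percent-scale RSDs of real peak areas far better than additive noise).
Volume scaling is exactly linear; real small nonlinearities with volume
are deliberately not modelled.  Everything is reproducible from a
single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import refdata
from .records import InjectionRecord, QamsError

__all__ = [
    "PeakSpec",
    "Chromatogram",
    "PeakArea",
    "StudyTruth",
    "StudyBundle",
    "RecoverySet",
    "simulate_chromatogram",
    "integrate_peaks",
    "snr",
    "default_study_truth",
    "generate_study",
]

REFERENCE_VOLUME_UL = 10.0


# ---------------------------------------------------------------------------
# signal level
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSpec:
    """Ground truth for one Gaussian peak.

    The analytic peak area is ``true_amount × height_scale`` (detector
    units × min); the peak profile is a normalised Gaussian scaled to
    that area.
    """

    analyte_id: str
    retention_time: float          # min
    width_sigma: float             # min
    true_amount: float             # µg on column
    height_scale: float = 1000.0   # detector units · min per µg

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise QamsError(
                f"peak {self.analyte_id!r}: retention time must be positive"
            )
        if self.width_sigma <= 0:
            raise QamsError(
                f"peak {self.analyte_id!r}: width sigma must be positive, "
                f"got {self.width_sigma}"
            )
        if self.true_amount < 0:
            raise QamsError(f"peak {self.analyte_id!r}: negative amount")

    @property
    def area(self) -> float:
        """Closed-form peak area (detector units × min)."""
        return self.true_amount * self.height_scale


@dataclass(frozen=True)
class Chromatogram:
    """A simulated detector trace with its ground-truth annotation."""

    time_min: np.ndarray
    signal: np.ndarray
    truth: tuple[PeakSpec, ...]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if len(t) != len(s):
            raise QamsError("time grid and signal lengths differ")
        if len(t) < 2:
            raise QamsError("time grid needs at least two points")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=0):
            raise QamsError("time grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(s)):
            raise QamsError("signal contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.time_min[1] - self.time_min[0])


@dataclass(frozen=True)
class PeakArea:
    """One integrated window: baseline-corrected trapezoidal area."""

    analyte_id: str
    area: float
    clipped: bool = False   # True when a negative integral was clipped to 0


def simulate_chromatogram(
    specs: Sequence[PeakSpec],
    *,
    t_start: float = 0.0,
    t_end: float = 60.0,
    dt: float = 0.01,
    noise_sd: float = 0.0,
    baseline_intercept: float = 0.0,
    baseline_drift: float = 0.0,
    seed: int = 0,
) -> Chromatogram:
    """Render Gaussian peaks onto a uniform time grid.

    signal(t) = Σ area_i · N(t; rt_i, σ_i) + (b0 + b1·t) + ε,
    ε ~ iid Normal(0, noise_sd²).  Peaks may overlap freely; the grid
    must cover every peak's retention time ± 5σ so the rendered area
    matches the closed form.
    """
    if dt <= 0:
        raise QamsError(f"grid spacing must be positive, got {dt}")
    if t_end <= t_start:
        raise QamsError("t_end must exceed t_start")
    if noise_sd < 0:
        raise QamsError("noise_sd must be non-negative")
    for spec in specs:
        if spec.retention_time - 5 * spec.width_sigma < t_start or (
            spec.retention_time + 5 * spec.width_sigma > t_end
        ):
            raise QamsError(
                f"grid [{t_start}, {t_end}] does not cover peak "
                f"{spec.analyte_id!r} at {spec.retention_time} ± 5σ"
            )

    n = int(round((t_end - t_start) / dt)) + 1
    t = t_start + dt * np.arange(n)
    signal = baseline_intercept + baseline_drift * t
    for spec in specs:
        z = (t - spec.retention_time) / spec.width_sigma
        signal = signal + spec.area / (
            spec.width_sigma * math.sqrt(2 * math.pi)
        ) * np.exp(-0.5 * z**2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    return Chromatogram(
        time_min=t,
        signal=signal,
        truth=tuple(specs),
        noise_sd=noise_sd,
        seed=seed,
    )


def _window_slice(chrom: Chromatogram, lo: float, hi: float, label: str) -> slice:
    t = chrom.time_min
    if lo >= hi:
        raise QamsError(f"window {label!r}: empty interval ({lo}, {hi})")
    if lo < t[0] or hi > t[-1]:
        raise QamsError(
            f"window {label!r} ({lo}, {hi}) falls outside the time grid "
            f"[{t[0]}, {t[-1]}]"
        )
    i0 = int(np.searchsorted(t, lo, side="left"))
    i1 = int(np.searchsorted(t, hi, side="right"))
    if i1 - i0 < 2:
        raise QamsError(f"window {label!r} spans fewer than two grid points")
    return slice(i0, i1)


def integrate_peaks(
    chrom: Chromatogram, windows: Mapping[str, tuple[float, float]]
) -> list[PeakArea]:
    """Baseline-corrected trapezoidal integration over per-analyte windows.

    The local baseline is the straight line through the signal at the
    two window endpoints; windows must be non-overlapping and inside
    the grid.  Negative integrals (possible in pure noise) are clipped
    to zero and flagged.
    """
    intervals = sorted(
        ((lo, hi, aid) for aid, (lo, hi) in windows.items()), key=lambda w: w[0]
    )
    for (_, hi_a, aid_a), (lo_b, _, aid_b) in zip(intervals, intervals[1:]):
        if lo_b < hi_a:
            raise QamsError(
                f"integration windows {aid_a!r} and {aid_b!r} overlap"
            )

    out: list[PeakArea] = []
    for aid, (lo, hi) in windows.items():
        sl = _window_slice(chrom, lo, hi, aid)
        t = chrom.time_min[sl]
        y = chrom.signal[sl]
        baseline = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
        area = float(np.trapezoid(y - baseline, t))
        if area < 0:
            out.append(PeakArea(aid, 0.0, clipped=True))
        else:
            out.append(PeakArea(aid, area))
    return out


def snr(
    chrom: Chromatogram,
    window: tuple[float, float],
    noise_region: tuple[float, float],
) -> float:
    """Signal-to-noise ratio of one peak.

    Peak height above the local (endpoint-interpolated) baseline in
    ``window`` divided by the standard deviation of the raw signal in a
    peak-free ``noise_region``.  Returns ``inf`` for a noiseless trace.
    """
    sl = _window_slice(chrom, *window, "peak window")
    t = chrom.time_min[sl]
    y = chrom.signal[sl]
    baseline = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    height = float(np.max(y - baseline))
    nsl = _window_slice(chrom, *noise_region, "noise region")
    noise = float(np.std(chrom.signal[nsl], ddof=1))
    if noise == 0.0:
        return math.inf
    return height / noise


# ---------------------------------------------------------------------------
# study level
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyTruth:
    """Everything the generator needs to fabricate one study.

    ``contents`` holds the true per-sample, per-analyte contents in
    mg per g of powder; ``calibration`` the true detector response
    (slope in area per µg/mL, intercept in area) per analyte;
    ``calibration_ranges`` the concentration span (µg/mL) over which
    standards are prepared.  ``noise_cv`` is the coefficient of
    variation of the multiplicative area noise (0 disables noise).
    """

    contents: Mapping[str, Mapping[str, float]]
    calibration: Mapping[str, tuple[float, float]]
    calibration_ranges: Mapping[str, tuple[float, float]]
    noise_cv: float = 0.02
    prep_mass_g: float = 0.1
    prep_volume_ml: float = 10.0
    injection_volumes_ul: tuple[float, ...] = refdata.RCF_VOLUMES_UL
    reference_volume_ul: float = REFERENCE_VOLUME_UL
    n_calibration_levels: int = 6
    n_replicates: int = 3
    n_validation_replicates: int = 6
    day_effect_cv: float = 0.01
    marker_id: str = refdata.MARKER_ID
    repeat_sample_id: str = "S7"
    instruments: tuple[tuple[str, str], ...] = (
        ("instrument-A", "column-1"),
        ("instrument-A", "column-2"),
        ("instrument-B", "column-1"),
        ("instrument-B", "column-2"),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_cv <= 0.2:
            raise QamsError(f"noise CV must lie in [0, 0.2], got {self.noise_cv}")
        if self.prep_mass_g <= 0 or self.prep_volume_ml <= 0:
            raise QamsError("prep mass and volume must be positive")
        if any(v <= 0 for v in self.injection_volumes_ul):
            raise QamsError("injection volumes must be positive")
        for sample, row in self.contents.items():
            for aid, c in row.items():
                if c < 0:
                    raise QamsError(
                        f"negative content for {sample}/{aid}: {c}"
                    )
        for aid in self.panel:
            if aid not in self.calibration:
                raise QamsError(f"no calibration truth for analyte {aid!r}")
        if self.marker_id not in self.calibration:
            raise QamsError(f"marker {self.marker_id!r} has no calibration truth")

    @property
    def panel(self) -> tuple[str, ...]:
        first = next(iter(self.contents.values()))
        return tuple(first.keys())

    def extract_concentration(self, content_mg_per_g: float) -> float:
        """True extract concentration (µg/mL) for a content (mg/g)."""
        return content_mg_per_g * self.prep_mass_g * 1000.0 / self.prep_volume_ml


@dataclass(frozen=True)
class RecoverySet:
    """Spike-recovery raw material for one analyte: known base and
    spiked amounts (mg) in the weighed portion, and the observed areas
    of the spiked extract (reference volume)."""

    analyte_id: str
    base_amount_mg: float
    spiked_amount_mg: float
    prep_mass_g: float
    areas: tuple[float, ...]


@dataclass(frozen=True)
class StudyBundle:
    """All records one simulated study produces."""

    truth: StudyTruth
    calibration_series: dict[str, list[tuple[float, float]]]
    standard_concentrations: dict[str, float]
    standard_runs: list[InjectionRecord]
    sample_runs: list[InjectionRecord]
    precision_areas: dict[str, dict[str, list[float]]]     # analyte -> day -> areas
    stability_areas: dict[str, list[tuple[float, float]]]  # analyte -> (hour, area)
    repeatability_areas: dict[str, list[float]]            # analyte -> areas (indep. preps)
    recovery_sets: dict[str, RecoverySet]
    warnings: tuple[str, ...] = field(default_factory=tuple)


def default_study_truth(
    seed: int = 0,
    *,
    noise_cv: float = 0.02,
    zero_intercepts: bool = False,
    samples: Iterable[str] | None = None,
) -> StudyTruth:
    """The default simulated study: published calibration parameters as
    detector truth and the thirteen published batch compositions as
    sample truth (cells reported unquantifiable become zero content).

    ``zero_intercepts`` replaces the small published intercepts with
    zero, giving an exactly proportional detector — the regime in which
    single-marker quantification is algebraically exact (see the
    methods note).
    """
    contents = {
        sample: {aid: (row[aid] or 0.0) for aid in refdata.PANEL}
        for sample, row in refdata.ES_CONTENTS.items()
        if samples is None or sample in set(samples)
    }
    calibration = {
        aid: (p["slope"], 0.0 if zero_intercepts else p["intercept"])
        for aid, p in refdata.REFERENCE_CALIBRATIONS.items()
    }
    ranges = {
        aid: p["range"] for aid, p in refdata.REFERENCE_CALIBRATIONS.items()
    }
    return StudyTruth(
        contents=contents,
        calibration=calibration,
        calibration_ranges=ranges,
        noise_cv=noise_cv,
        seed=seed,
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def generate_study(truth: StudyTruth) -> StudyBundle:
    """Fabricate every record set the analysis pipeline consumes.

    Deterministic per seed: repeated calls with an equal ``truth``
    return identical bundles.  Standard mixes are prepared at the
    geometric midpoint of each analyte's calibration range; sample
    extracts whose true concentration falls outside that range get a
    warning attached to the record (and collected on the bundle).
    """
    rng = np.random.default_rng(truth.seed)
    panel = truth.panel
    cal = truth.calibration
    rts = refdata.DEFAULT_RETENTION_TIMES

    def expected_area(aid: str, conc: float, volume: float) -> float:
        slope, intercept = cal[aid]
        return (slope * conc + intercept) * volume / truth.reference_volume_ul

    def noisy(values: np.ndarray | float, n: int = 1) -> np.ndarray:
        return np.atleast_1d(values) * _lognormal_factors(rng, truth.noise_cv, n)

    # calibration series: geometric level spacing across each range
    calibration_series: dict[str, list[tuple[float, float]]] = {}
    for aid in panel:
        lo, hi = truth.calibration_ranges[aid]
        levels = np.geomspace(lo, hi, truth.n_calibration_levels)
        areas = noisy(
            [expected_area(aid, c, truth.reference_volume_ul) for c in levels],
            truth.n_calibration_levels,
        )
        calibration_series[aid] = list(zip(levels.tolist(), areas.tolist()))

    # one mixed standard, concentration per analyte at geometric mid-range
    standard_concentrations = {
        aid: float(np.sqrt(np.prod(truth.calibration_ranges[aid])))
        for aid in panel
    }

    primary_instrument, primary_column = truth.instruments[0]
    standard_runs: list[InjectionRecord] = []
    for instrument, column in truth.instruments:
        volumes = (
            truth.injection_volumes_ul
            if (instrument, column) == (primary_instrument, primary_column)
            else (truth.reference_volume_ul,)
        )
        for volume in volumes:
            for rep in range(1, truth.n_replicates + 1):
                run_id = f"std-{instrument}-{column}-v{volume:g}-r{rep}"
                for aid in panel:
                    area = float(
                        noisy(expected_area(aid, standard_concentrations[aid], volume))[0]
                    )
                    standard_runs.append(
                        InjectionRecord(
                            run_id=run_id,
                            sample_id="STD",
                            instrument_id=instrument,
                            column_id=column,
                            injection_volume_ul=float(volume),
                            analyte_id=aid,
                            retention_time_min=rts.get(aid, 30.0),
                            area=area,
                        )
                    )

    # sample runs at the reference volume on the primary instrument
    sample_runs: list[InjectionRecord] = []
    warnings: list[str] = []
    for sample, row in truth.contents.items():
        concs = {aid: truth.extract_concentration(row[aid]) for aid in panel}
        for rep in range(1, truth.n_replicates + 1):
            run_id = f"{sample}-r{rep}"
            for aid in panel:
                conc = concs[aid]
                lo, hi = truth.calibration_ranges[aid]
                note = "blank" if conc == 0 else ""
                if conc > 0 and not lo <= conc <= hi:
                    note = "concentration_outside_calibration_range"
                    if rep == 1:
                        warnings.append(
                            f"{sample}/{aid}: true concentration "
                            f"{conc:.4g} µg/mL outside calibration range "
                            f"({lo:g}, {hi:g})"
                        )
                area = float(
                    noisy(expected_area(aid, conc, truth.reference_volume_ul))[0]
                )
                sample_runs.append(
                    InjectionRecord(
                        run_id=run_id,
                        sample_id=sample,
                        instrument_id=primary_instrument,
                        column_id=primary_column,
                        injection_volume_ul=truth.reference_volume_ul,
                        analyte_id=aid,
                        retention_time_min=rts.get(aid, 30.0),
                        area=area,
                        note=note,
                    )
                )

    # precision: six injections of the mixed standard on each of two days,
    # with a small multiplicative between-day effect per analyte
    precision_areas: dict[str, dict[str, list[float]]] = {}
    for aid in panel:
        base = expected_area(
            aid, standard_concentrations[aid], truth.reference_volume_ul
        )
        day2_shift = float(_lognormal_factors(rng, truth.day_effect_cv, 1)[0])
        precision_areas[aid] = {
            "day1": noisy(base, truth.n_validation_replicates).tolist(),
            "day2": (day2_shift * noisy(base, truth.n_validation_replicates)).tolist(),
        }

    # stability: the repeat sample re-injected over 24 h, drift-free truth
    stability_hours = (0.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    repeat_id = (
        truth.repeat_sample_id
        if truth.repeat_sample_id in truth.contents
        else next(iter(truth.contents))
    )
    repeat_row = truth.contents[repeat_id]
    stability_areas: dict[str, list[tuple[float, float]]] = {}
    for aid in panel:
        conc = truth.extract_concentration(repeat_row[aid])
        base = expected_area(aid, conc, truth.reference_volume_ul)
        areas = noisy(base, len(stability_hours))
        stability_areas[aid] = list(zip(stability_hours, areas.tolist()))

    # repeatability: six independent preparations of the repeat sample
    repeatability_areas: dict[str, list[float]] = {}
    for aid in panel:
        conc = truth.extract_concentration(repeat_row[aid])
        base = expected_area(aid, conc, truth.reference_volume_ul)
        repeatability_areas[aid] = noisy(
            base, truth.n_validation_replicates
        ).tolist()

    # spike recovery: 0.50 g of the repeat sample spiked at ~100% of the
    # native amount, measured through the full area pathway
    recovery_mass_g = 0.5
    recovery_sets: dict[str, RecoverySet] = {}
    for aid in panel:
        base_mg = repeat_row[aid] * recovery_mass_g
        if base_mg <= 0:
            continue
        spike_mg = base_mg
        total_conc = (base_mg + spike_mg) * 1000.0 / truth.prep_volume_ml
        base = expected_area(aid, total_conc, truth.reference_volume_ul)
        areas = noisy(base, truth.n_validation_replicates)
        recovery_sets[aid] = RecoverySet(
            analyte_id=aid,
            base_amount_mg=base_mg,
            spiked_amount_mg=spike_mg,
            prep_mass_g=recovery_mass_g,
            areas=tuple(areas.tolist()),
        )

    return StudyBundle(
        truth=truth,
        calibration_series=calibration_series,
        standard_concentrations=standard_concentrations,
        standard_runs=standard_runs,
        sample_runs=sample_runs,
        precision_areas=precision_areas,
        stability_areas=stability_areas,
        repeatability_areas=repeatability_areas,
        recovery_sets=recovery_sets,
        warnings=tuple(warnings),
    )


def chromatogram_for_run(
    truth: StudyTruth,
    sample_id: str,
    *,
    width_sigma: float = 0.15,
    noise_sd: float = 2.0,
    seed: int | None = None,
) -> tuple[Chromatogram, dict[str, tuple[float, float]]]:
    """Render a full-trace chromatogram for one sample of a study.

    Convenience bridge between the study layer (areas) and the signal
    layer (traces): peak areas are set to the noiseless expected areas
    of the sample's analytes.  Returns the trace and per-analyte
    integration windows (± 4σ).
    """
    row = truth.contents[sample_id]
    specs = []
    windows = {}
    for aid in truth.panel:
        conc = truth.extract_concentration(row[aid])
        slope, intercept = truth.calibration[aid]
        area = max(slope * conc + intercept, 0.0)
        if area == 0.0:
            continue
        rt = refdata.DEFAULT_RETENTION_TIMES.get(aid, 30.0)
        specs.append(
            PeakSpec(
                analyte_id=aid,
                retention_time=rt,
                width_sigma=width_sigma,
                true_amount=area,
                height_scale=1.0,
            )
        )
        windows[aid] = (rt - 4 * width_sigma, rt + 4 * width_sigma)
    chrom = simulate_chromatogram(
        specs,
        noise_sd=noise_sd,
        seed=truth.seed if seed is None else seed,
    )
    return chrom, windows
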