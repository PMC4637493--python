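"""Signal- and study-level simulator checks: closed-form peak areas,
integration bias, noise calibration, volume linearity, determinism."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import qamskit as qk
from qamskit.records import QamsError
from qamskit.simulate import PeakSpec, chromatogram_for_run


def _gauss_sum(specs):
    def f(t):
        return sum(
            s.area / (s.width_sigma * math.sqrt(2 * math.pi))
            * math.exp(-0.5 * ((t - s.retention_time) / s.width_sigma) ** 2)
            for s in specs
        )
    return f


class TestSimulateChromatogram:
    def test_single_peak_matches_closed_form_area(self):
        spec = PeakSpec("bavachin", 24.8, 0.15, 3.2, 1500.0)
        chrom = qk.simulate_chromatogram([spec], noise_sd=0.0)
        total = np.trapezoid(chrom.signal, chrom.time_min)
        assert total == pytest.approx(spec.area, rel=1e-3)

    def test_zero_peaks_returns_baseline_exactly(self):
        chrom = qk.simulate_chromatogram(
            [], noise_sd=0.0, baseline_intercept=5.0, baseline_drift=0.2
        )
        np.testing.assert_allclose(chrom.signal, 5.0 + 0.2 * chrom.time_min)

    def test_overlapping_peaks_match_quadrature_oracle(self):
        # two peaks closer than 2 sigma: total mass must still match an
        # independent adaptive-quadrature integral of the analytic model
        specs = [
            PeakSpec("a", 30.0, 0.2, 2.0, 1000.0),
            PeakSpec("b", 30.3, 0.2, 1.0, 1000.0),
        ]
        chrom = qk.simulate_chromatogram(specs, noise_sd=0.0)
        oracle, err = quad(_gauss_sum(specs), 0.0, 60.0, limit=200)
        total = np.trapezoid(chrom.signal, chrom.time_min)
        assert total == pytest.approx(oracle, rel=1e-3)
        assert oracle == pytest.approx(sum(s.area for s in specs), rel=1e-6)

    def test_reproducible_for_fixed_seed(self):
        spec = PeakSpec("a", 30.0, 0.2, 2.0, 1000.0)
        c1 = qk.simulate_chromatogram([spec], noise_sd=3.0, seed=42)
        c2 = qk.simulate_chromatogram([spec], noise_sd=3.0, seed=42)
        np.testing.assert_array_equal(c1.signal, c2.signal)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt": 0.0},
            {"dt": -0.1},
            {"t_start": 10.0, "t_end": 5.0},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_grid_rejected(self, kwargs):
        with pytest.raises(QamsError):
            qk.simulate_chromatogram([], **kwargs)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(QamsError, match="sigma"):
            PeakSpec("a", 30.0, 0.0, 2.0)

    def test_grid_must_cover_peak(self):
        spec = PeakSpec("a", 59.9, 0.3, 1.0)
        with pytest.raises(QamsError, match="cover"):
            qk.simulate_chromatogram([spec])


class TestIntegratePeaks:
    def test_noiseless_gaussian_recovered_within_half_percent(self):
        spec = PeakSpec("a", 30.0, 0.15, 2.5, 1200.0)
        chrom = qk.simulate_chromatogram([spec], noise_sd=0.0)
        (res,) = qk.integrate_peaks(chrom, {"a": (29.0, 31.0)})
        assert res.area == pytest.approx(spec.area, rel=5e-3)
        assert not res.clipped

    def test_flat_signal_gives_zero_everywhere(self):
        chrom = qk.simulate_chromatogram([], baseline_intercept=10.0)
        results = qk.integrate_peaks(
            chrom, {"w1": (5.0, 7.0), "w2": (20.0, 25.0)}
        )
        assert all(r.area == 0.0 for r in results)

    def test_baseline_drift_is_subtracted(self):
        spec = PeakSpec("a", 30.0, 0.15, 2.5, 1200.0)
        chrom = qk.simulate_chromatogram(
            [spec], baseline_intercept=50.0, baseline_drift=1.5
        )
        (res,) = qk.integrate_peaks(chrom, {"a": (29.0, 31.0)})
        assert res.area == pytest.approx(spec.area, rel=5e-3)

    def test_integration_unbiased_over_seeds(self):
        # Monte-Carlo oracle: with white noise the recovered areas must
        # scatter around the analytic area without systematic bias
        spec = PeakSpec("a", 30.0, 0.15, 2.5, 1200.0)
        areas = []
        for seed in range(50):
            chrom = qk.simulate_chromatogram([spec], noise_sd=10.0, seed=seed)
            (res,) = qk.integrate_peaks(chrom, {"a": (29.0, 31.0)})
            areas.append(res.area)
        areas = np.array(areas)
        se = areas.std(ddof=1) / math.sqrt(len(areas))
        assert abs(areas.mean() - spec.area) <= 2 * se

    def test_negative_window_area_clipped_and_flagged(self):
        chrom = qk.simulate_chromatogram(
            [PeakSpec("a", 30.0, 0.15, 2.5, 1200.0)]
        )
        # window starting on the peak's falling shoulder: the endpoint
        # baseline sits above the decaying interior signal
        (res,) = qk.integrate_peaks(chrom, {"x": (30.45, 34.0)})
        assert res.area == 0.0 and res.clipped

    def test_window_outside_grid_names_window(self):
        chrom = qk.simulate_chromatogram([])
        with pytest.raises(QamsError, match="edge"):
            qk.integrate_peaks(chrom, {"edge": (59.0, 61.0)})

    def test_overlapping_windows_rejected(self):
        chrom = qk.simulate_chromatogram([])
        with pytest.raises(QamsError, match="overlap"):
            qk.integrate_peaks(chrom, {"a": (10.0, 12.0), "b": (11.5, 13.0)})


class TestSnr:
    def test_noiseless_trace_reports_infinite(self):
        chrom = qk.simulate_chromatogram([PeakSpec("a", 30.0, 0.2, 1.0)])
        assert math.isinf(qk.snr(chrom, (29.0, 31.0), (5.0, 10.0)))

    def test_matches_brute_force_recomputation(self):
        spec = PeakSpec("a", 30.0, 0.2, 1.0, 1000.0)
        chrom = qk.simulate_chromatogram([spec], noise_sd=4.0, seed=3)
        got = qk.snr(chrom, (29.0, 31.0), (5.0, 10.0))
        t, y = chrom.time_min, chrom.signal
        win = (t >= 29.0) & (t <= 31.0)
        tw, yw = t[win], y[win]
        base = yw[0] + (yw[-1] - yw[0]) * (tw - tw[0]) / (tw[-1] - tw[0])
        height = np.max(yw - base)
        noise = np.std(y[(t >= 5.0) & (t <= 10.0)], ddof=1)
        assert got == pytest.approx(height / noise, rel=1e-12)

    def test_constructed_ratio(self):
        # peak height ~100 over a flat baseline, noise sd 5 by construction
        sigma = 0.2
        amount = 100.0 * sigma * math.sqrt(2 * math.pi)
        spec = PeakSpec("a", 30.0, sigma, amount, 1.0)
        chrom = qk.simulate_chromatogram([spec], noise_sd=0.0)
        rng = np.random.default_rng(0)
        noisy = qk.Chromatogram(
            time_min=chrom.time_min,
            signal=chrom.signal
            + rng.normal(0, 5.0, len(chrom.signal)) * (chrom.time_min < 20),
            truth=chrom.truth,
            noise_sd=5.0,
            seed=0,
        )
        got = qk.snr(noisy, (29.0, 31.0), (5.0, 15.0))
        assert got == pytest.approx(20.0, rel=0.15)


class TestGenerateStudy:
    def test_prep_arithmetic(self):
        truth = qk.default_study_truth(noise_cv=0.0)
        assert truth.extract_concentration(4.367) == pytest.approx(43.67)

    def test_noiseless_area_is_linear_response(self):
        # bavachin at 43.67 µg/mL through the published line, by hand
        truth = qk.default_study_truth(seed=0, noise_cv=0.0)
        bundle = qk.generate_study(truth)
        rec = next(
            r for r in bundle.sample_runs
            if r.sample_id == "S1" and r.analyte_id == "bavachin"
        )
        assert rec.area == pytest.approx(9536.0 * 43.67 - 72.258, rel=1e-12)

    def test_zero_content_gives_intercept_only_response(self):
        truth = qk.default_study_truth(seed=0, noise_cv=0.0)
        bundle = qk.generate_study(truth)
        rec = next(
            r for r in bundle.sample_runs
            if r.sample_id == "S1" and r.analyte_id == "isobavachin"
        )
        slope, intercept = truth.calibration["isobavachin"]
        assert rec.area == pytest.approx(intercept)
        assert rec.note == "blank"

    def test_areas_scale_linearly_with_injection_volume(self):
        truth = qk.default_study_truth(seed=0, noise_cv=0.0)
        bundle = qk.generate_study(truth)
        by_volume = {}
        for r in bundle.standard_runs:
            if r.analyte_id == "bavachin" and r.run_id.endswith("r1"):
                by_volume[r.injection_volume_ul] = r.area
        assert by_volume[20.0] == pytest.approx(2 * by_volume[10.0], rel=1e-12)
        assert by_volume[2.0] == pytest.approx(2 * by_volume[1.0], rel=1e-12)

    def test_fixed_seed_bit_identical(self):
        t1 = qk.default_study_truth(seed=9, noise_cv=0.02)
        t2 = qk.default_study_truth(seed=9, noise_cv=0.02)
        b1, b2 = qk.generate_study(t1), qk.generate_study(t2)
        assert b1.sample_runs == b2.sample_runs
        assert b1.standard_runs == b2.standard_runs
        assert b1.calibration_series == b2.calibration_series

    def test_area_noise_cv_calibrated(self):
        # empirical RSD of replicated areas at CV 2% must sit near 2%
        truth = qk.default_study_truth(seed=3, noise_cv=0.02)
        import numpy as np
        from qamskit.simulate import _lognormal_factors

        rng = np.random.default_rng(3)
        factors = _lognormal_factors(rng, 0.02, 100)
        rsd = 100 * factors.std(ddof=1) / factors.mean()
        assert 1.5 <= rsd <= 2.5

    def test_out_of_range_concentration_warns_on_record(self):
        contents = {"X1": {"bavachin": 50.0, "neobavaisoflavone": 5.0}}
        base = qk.default_study_truth(noise_cv=0.0)
        truth = qk.StudyTruth(
            contents=contents,
            calibration=base.calibration,
            calibration_ranges=base.calibration_ranges,
            noise_cv=0.0,
        )
        bundle = qk.generate_study(truth)
        rec = next(
            r for r in bundle.sample_runs if r.analyte_id == "bavachin"
        )
        # 50 mg/g -> 500 µg/mL, above the 300 µg/mL calibration ceiling
        assert rec.note == "concentration_outside_calibration_range"
        assert any("bavachin" in w for w in bundle.warnings)

    def test_noise_cv_bound_enforced(self):
        with pytest.raises(QamsError, match="noise CV"):
            qk.default_study_truth(noise_cv=0.5)


def test_chromatogram_bridge_recovers_study_areas():
    """Integrated areas of a rendered sample trace match the peak-table
    areas the study layer would emit for the same sample."""
    truth = qk.default_study_truth(seed=0, noise_cv=0.0)
    chrom, windows = chromatogram_for_run(truth, "S4", noise_sd=0.0)
    results = {r.analyte_id: r.area for r in qk.integrate_peaks(chrom, windows)}
    for aid, area in results.items():
        conc = truth.extract_concentration(truth.contents["S4"][aid])
        slope, intercept = truth.calibration[aid]
        expected = slope * conc + intercept
        assert area == pytest.approx(expected, rel=2e-3), aid
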