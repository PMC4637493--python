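"""Single-marker quantification: the correction-factor formula, its
summaries against the published tables, the algebraic round trip, and
the end-to-end identity on proportional detectors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import qamskit as qk
from qamskit import refdata
from qamskit.qams import round_sig
from qamskit.records import QamsError, SamplePrep

positive = st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)


class TestComputeRcf:
    def test_symmetric_inputs_give_unity(self):
        assert qk.compute_rcf(50.0, 1234.0, 50.0, 1234.0) == 1.0

    def test_scaling_laws(self):
        base = qk.compute_rcf(100.0, 2e6, 80.0, 1e6)
        assert qk.compute_rcf(100.0, 2e6, 80.0, 2e6) == pytest.approx(2 * base)
        assert qk.compute_rcf(100.0, 4e6, 80.0, 1e6) == pytest.approx(base / 2)

    def test_published_slope_ratio_arithmetic(self):
        # equal concentrations on the published neobavaisoflavone and
        # bavachin response lines: f is the area ratio 953528/2806972
        a_k = 28072.0 * 100.0 - 228.09
        a_m = 9536.0 * 100.0 - 72.258
        f = qk.compute_rcf(100.0, a_k, 100.0, a_m)
        assert f == pytest.approx(953_527.742 / 2_806_971.91, rel=1e-9)
        assert round_sig(f, 4) == pytest.approx(0.3397)

    @pytest.mark.parametrize("bad", ["W_k", "A_k", "W_m", "A_m"])
    def test_nonpositive_input_names_symbol(self, bad):
        args = {"W_k": 1.0, "A_k": 1.0, "W_m": 1.0, "A_m": 1.0}
        args[bad] = 0.0
        with pytest.raises(QamsError, match=bad):
            qk.compute_rcf(args["W_k"], args["A_k"], args["W_m"], args["A_m"])

    @given(positive, positive, positive, positive, positive)
    def test_invariant_to_common_rescaling(self, w_k, a_k, w_m, gain, scale):
        a_m = 3.21 * a_k
        f = qk.compute_rcf(w_k, a_k, w_m, a_m)
        assert qk.compute_rcf(w_k, gain * a_k, w_m, gain * a_m) == pytest.approx(
            f, rel=1e-9
        )
        assert qk.compute_rcf(
            scale * w_k, a_k, scale * w_m, a_m
        ) == pytest.approx(f, rel=1e-9)


class TestRcfSummary:
    def test_published_per_volume_columns_reproduced(self):
        # the per-volume f columns whose printed mean/RSD are exactly
        # recoverable from the rounded values
        cases = {
            "isobavachin": (0.683, 3.5),
            "bavachinin": (0.833, None),
            "isobavachalcone": (1.98, 2.3),
            "corylifol_a": (0.763, 2.7),
            "o_methylbavachalcone": (None, 3.6),
        }
        for aid, (mean, rsd) in cases.items():
            est = qk.rcf_summary(
                list(zip(map(str, refdata.RCF_VOLUMES_UL),
                         refdata.RCF_BY_VOLUME[aid])),
                analyte_id=aid, marker_id=refdata.MARKER_ID,
            )
            if mean is not None:
                assert round(est.mean_f, 3 if mean < 1 else 2) == mean, aid
            if rsd is not None:
                assert round(est.rsd_percent, 1) == rsd, aid

    def test_identical_values_have_zero_rsd(self):
        est = qk.rcf_summary([("a", 1.5), ("b", 1.5), ("c", 1.5)])
        assert est.rsd_percent == 0.0
        assert est.mean_f == 1.5

    def test_condition_order_preserved(self):
        est = qk.rcf_summary([("20 uL", 1.0), ("1 uL", 2.0)])
        assert [c for c, _ in est.per_condition_values] == ["20 uL", "1 uL"]

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(QamsError):
            qk.rcf_summary([("a", 1.0)])


class TestRcfRobustness:
    def test_published_instrument_column_spread(self):
        groups = {
            (i, c): f["isobavachin"]
            for (i, c), f in refdata.RCF_BY_INSTRUMENT.items()
        }
        res = qk.rcf_robustness(groups, analyte_id="isobavachin")
        assert res.spread_percent == pytest.approx(
            100 * (0.688 - 0.672) / np.mean([0.683, 0.676, 0.672, 0.688]),
            rel=1e-9,
        )
        assert round(res.spread_percent, 2) == 2.35

    def test_equal_groups_zero_spread(self):
        res = qk.rcf_robustness({("i1", "c1"): 1.0, ("i2", "c2"): 1.0})
        assert res.spread_percent == 0.0

    def test_two_group_construction(self):
        res = qk.rcf_robustness({("a", "x"): 1.0, ("b", "y"): 1.1})
        assert res.spread_percent == pytest.approx(100 * 0.1 / 1.05)


class TestQamsQuantify:
    @given(positive, positive, positive, positive)
    def test_algebraic_round_trip_exact(self, w_k, a_k, w_m, a_m):
        f = qk.compute_rcf(w_k, a_k, w_m, a_m)
        prep = SamplePrep(0.1, 10.0)
        res = qk.qams_quantify(f, a_m, w_k, a_k, prep)
        assert res.concentration_ug_per_ml == pytest.approx(w_m, rel=1e-12)

    def test_unit_factor(self):
        res = qk.qams_quantify(1.0, 500.0, 42.0, 500.0, SamplePrep(0.1, 10.0))
        assert res.concentration_ug_per_ml == pytest.approx(42.0)
        assert res.content_mg_per_g == pytest.approx(4.2)
        assert res.method == "qams"

    def test_nonpositive_f_rejected(self):
        with pytest.raises(QamsError, match="f"):
            qk.qams_quantify(0.0, 1.0, 1.0, 1.0, SamplePrep())


class TestAccuracy:
    @pytest.mark.parametrize(
        "w_qams, w_es, expected",
        [
            (4.229, 4.367, 96.84),    # published pair, bavachin-type cell
            (1.323, 1.208, 109.5),    # published upper extreme
            (2.925, 3.149, 92.89),    # published lower extreme
            (6.755, 6.847, 98.66),
            (9.932, 9.726, 102.1),
            (5.0, 5.0, 100.0),
        ],
    )
    def test_published_pairs_and_identity(self, w_qams, w_es, expected):
        assert qk.accuracy(w_qams, w_es) == pytest.approx(expected, abs=5e-3)

    def test_zero_reference_rejected(self):
        with pytest.raises(QamsError):
            qk.accuracy(1.0, 0.0)


class TestEndToEnd:
    def test_proportional_noiseless_pipeline_is_exact(self, proportional_bundle):
        """With a proportional detector (zero intercepts) and no noise,
        the single-marker route reproduces the external-standard
        contents exactly: every accuracy is 100%."""
        truth = proportional_bundle.truth
        cfg = qk.StudyConfig(noise_cv=0.0, seed=truth.seed)
        res = qk.run_pipeline(cfg, bundle=proportional_bundle, write=False)
        assert res.accuracy  # non-empty
        for rec in res.accuracy:
            assert rec.w_qams_mg_per_g == pytest.approx(
                rec.w_es_mg_per_g, rel=1e-9
            )
            assert rec.accuracy_percent == 100.0

    def test_published_intercepts_bias_below_two_per_mille(
        self, noiseless_bundle
    ):
        """The small published intercepts make the single-marker route
        only approximately exact; without noise the residual bias stays
        in the per-mille range."""
        cfg = qk.StudyConfig(noise_cv=0.0, seed=noiseless_bundle.truth.seed)
        res = qk.run_pipeline(cfg, bundle=noiseless_bundle, write=False)
        for rec in res.accuracy:
            assert abs(rec.w_qams_mg_per_g / rec.w_es_mg_per_g - 1) < 2e-3

    def test_rcf_constant_across_volumes_without_noise(self, noiseless_bundle):
        # volume scaling affects marker and analyte areas identically
        primary = noiseless_bundle.truth.instruments[0]
        runs = [
            r for r in noiseless_bundle.standard_runs
            if (r.instrument_id, r.column_id) == primary
        ]
        rcfs = qk.rcf_from_standards(
            runs, noiseless_bundle.standard_concentrations, refdata.MARKER_ID
        )
        for est in rcfs.values():
            assert est.rsd_percent == pytest.approx(0.0, abs=1e-9)
            assert len(est.per_condition_values) == len(refdata.RCF_VOLUMES_UL)

    def test_marker_missing_from_standards_aborts_with_name(
        self, noiseless_bundle
    ):
        runs = [
            r for r in noiseless_bundle.standard_runs
            if r.analyte_id != refdata.MARKER_ID
        ]
        with pytest.raises(QamsError, match="neobavaisoflavone"):
            qk.rcf_from_standards(
                runs, noiseless_bundle.standard_concentrations,
                refdata.MARKER_ID,
            )

    def test_excluded_analytes_absent_from_qams_results(self):
        cfg = qk.StudyConfig(noise_cv=0.0, seed=2)
        res = qk.run_pipeline(cfg, write=False)
        analytes = {r.analyte_id for r in res.qams_results}
        assert "corylin" not in analytes
        assert "bavachalcone" not in analytes
        assert refdata.MARKER_ID not in analytes
        assert analytes == set(refdata.QAMS_ANALYTES)

    def test_noisy_accuracies_concentrate_near_100(self):
        """With 2% area noise, shared sample areas cancel between the
        two routes, so accuracies spread by a few percent at most."""
        accs = []
        for seed in range(25):
            cfg = qk.StudyConfig(noise_cv=0.02, seed=seed)
            res = qk.run_pipeline(cfg, write=False)
            accs.extend(r.accuracy_percent for r in res.accuracy)
        accs = np.array(accs)
        assert np.mean((accs >= 92.0) & (accs <= 108.0)) >= 0.95
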