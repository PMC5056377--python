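"""Calibration, prediction, bookkeeping and reporting conventions."""

import math

import numpy as np
import pytest

from cystir import preprocess, quantify, synth
from cystir.errors import CalibrationError, ParameterError


class TestFitCalibration:
    def test_exact_line(self):
        m = quantify.fit_calibration([(1, 2.0), (2, 4.0), (3, 6.0)])
        assert m.slope == pytest.approx(2.0, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_line_through_origin_with_zero_point(self):
        m = quantify.fit_calibration([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert m.slope == pytest.approx(1.0, abs=1e-12)
        assert m.concentration_range == (0.0, 3.0)

    def test_slope_is_unweighted_through_origin_formula(self, rng):
        conc = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        resp = 2.3 * conc + rng.normal(0, 0.05, conc.size)
        m = quantify.fit_calibration(list(zip(conc, resp)))
        assert m.slope == pytest.approx(np.sum(conc * resp) / np.sum(conc ** 2),
                                        abs=1e-14)

    def test_slope_matches_dense_search_oracle(self, rng):
        conc = np.array([0.0, 1.0, 2.0, 3.0])
        resp = 1.7 * conc + rng.normal(0, 0.05, conc.size)
        m = quantify.fit_calibration(list(zip(conc, resp)))
        ks = np.linspace(0.5, 3.0, 2_500_001)
        sse = (np.sum(resp ** 2) - 2 * ks * np.sum(conc * resp)
               + ks ** 2 * np.sum(conc ** 2))
        assert m.slope == pytest.approx(ks[np.argmin(sse)], abs=1e-6)

    def test_all_zero_concentrations_degenerate(self):
        with pytest.raises(CalibrationError, match="degenerate"):
            quantify.fit_calibration([(0, 0.1), (0, 0.2)])

    def test_negative_slope_flagged_not_raised(self):
        m = quantify.fit_calibration([(1, -1.0), (2, -2.0)])
        assert m.slope < 0
        assert any("slope" in w for w in m.warnings)

    def test_json_round_trip(self, tmp_path):
        m = quantify.fit_calibration([(1, 2.0), (2, 4.1), (3, 5.9)],
                                     meta={"sg_window_points": 9})
        p = tmp_path / "cal.json"
        m.to_json(p)
        back = quantify.CalibrationModel.from_json(p)
        assert back.slope == m.slope
        assert back.residual_sd == m.residual_sd
        assert back.meta["sg_window_points"] == 9


class TestPredict:
    def test_inverts_slope(self):
        m = quantify.fit_calibration([(1, 2.0), (2, 4.0), (3, 6.0)])
        pred = quantify.predict_concentration(m, m.slope * 1.5)
        assert pred.concentration_mM == pytest.approx(1.5, abs=1e-12)
        assert not pred.extrapolated

    def test_non_positive_response_clips_to_zero(self):
        m = quantify.fit_calibration([(1, 2.0), (2, 4.0), (3, 6.0)])
        assert quantify.predict_concentration(m, -0.5).concentration_mM == 0.0

    def test_extrapolation_above_range_flagged(self):
        m = quantify.fit_calibration([(1, 2.0), (2, 4.0), (3, 6.0)])
        pred = quantify.predict_concentration(m, m.slope * 4.0)
        assert pred.extrapolated

    def test_invalid_model_rejected(self):
        m = quantify.fit_calibration([(1, -1.0), (2, -2.0)])
        with pytest.raises(CalibrationError, match="slope"):
            quantify.predict_concentration(m, 1.0)

    def test_predict_fit_identity_on_noiseless_line(self):
        for slope in (0.3, 1.0, 7.5):
            series = [(c, slope * c) for c in (0.0, 1.0, 2.0, 3.0)]
            m = quantify.fit_calibration(series)
            for c in (0.25, 1.7, 2.9):
                pred = quantify.predict_concentration(m, slope * c)
                assert pred.concentration_mM == pytest.approx(c, rel=1e-12)

    def test_closed_loop_recovery_at_clinical_maximum(self, library, grid, refs):
        # the highest level seen clinically, 3.1 mM, recovered within 0.15 mM
        cal = synth.generate_calibration_series(
            [0, 0.5, 1, 1.5, 2, 2.5, 3], seed=23)
        model, _ = quantify.calibrate_spectra(cal)
        spec = synth.SampleSpec(concentrations={"cystine": 3.1},
                                baseline_coeffs=(1e-4, 2e-4, -3e-4),
                                noise_sd=synth.DEFAULT_NOISE_SD,
                                vapour_factor=0.2, seed=91)
        film = synth.generate_sample(spec, library, grid)
        corrected, _ = preprocess.subtract_atmosphere(film, refs,
                                                      include_water=False)
        resp = preprocess.cystine_response(
            preprocess.second_derivative(corrected))
        pred = quantify.predict_concentration(model, resp)
        assert pred.concentration_mM == pytest.approx(3.1, abs=0.15)


class TestDilution:
    def test_protocol_identity(self):
        assert quantify.apply_dilution(2.0, 1.0, 1.0) == 2.0

    def test_half_volume_resuspension(self):
        assert quantify.apply_dilution(2.0, 1.0, 0.5) == pytest.approx(1.0)

    def test_zero_concentration(self):
        assert quantify.apply_dilution(0.0, 0.3, 1.7) == 0.0

    @pytest.mark.parametrize("vols", [(0.0, 1.0), (1.0, -1.0)])
    def test_non_positive_volumes_rejected(self, vols):
        with pytest.raises(ParameterError):
            quantify.apply_dilution(1.0, *vols)


class TestReportSample:
    def test_triplicate_arithmetic(self):
        r = quantify.report_sample("P1", (2.0, 2.1, 2.2), creatinine_mM=10.0)
        assert r.insoluble_cystine_mM == pytest.approx(2.1)
        assert r.sem_mM == pytest.approx(0.1 / math.sqrt(3), abs=1e-9)
        assert r.sem_mM == pytest.approx(0.0577, abs=1e-4)
        assert r.detected
        assert r.total_cystine_mM == pytest.approx(3.1)
        assert r.ratio_uM_per_mM == pytest.approx(210.0)

    def test_undetected_sample_is_censored(self):
        r = quantify.report_sample("N1", (0.0, 0.0, 0.0))
        assert not r.detected
        assert r.insoluble_cystine_mM == 0.0
        assert r.censored
        assert r.total_cystine_mM == 0.5
        assert r.censored_halfwidth_mM == 0.5

    def test_zero_creatinine_flags_ratio_undefined(self):
        r = quantify.report_sample("P2", (1.0,), creatinine_mM=0.0)
        assert r.ratio_undefined
        assert r.ratio_uM_per_mM is None

    def test_detection_threshold_applied_to_mean(self):
        r = quantify.report_sample("P3", (0.02, 0.03, 0.01),
                                   detection_threshold_mM=0.05)
        assert not r.detected
        r2 = quantify.report_sample("P3", (0.06, 0.07, 0.05),
                                    detection_threshold_mM=0.05)
        assert r2.detected

    def test_requires_a_replicate(self):
        with pytest.raises(ParameterError, match="replicate"):
            quantify.report_sample("P4", ())


class TestSpotCapacity:
    def test_worked_example_value(self):
        cap = quantify.spot_capacity(193.0, 1.0, 3.0)
        assert cap == pytest.approx(60.8, abs=0.05)
        assert round(cap, -1) == 60.0

    def test_height_linearity(self):
        assert quantify.spot_capacity(193.0, 2.0, 3.0) == pytest.approx(
            2 * quantify.spot_capacity(193.0, 1.0, 3.0), rel=1e-12)

    def test_consistent_unit_rescaling_invariance(self):
        base = quantify.spot_capacity(193.0, 1.0, 3.0)
        for s in (0.5, 2.0, 10.0):
            scaled = quantify.spot_capacity(193.0 * s ** 3, 1.0 * s, 3.0 * s)
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_equivalent_aliquot(self):
        # 5 uL of a 12 mM suspension carries the same ~60 nmol
        amount = quantify.aliquot_amount_nmol(5.0, 12.0)
        assert amount == pytest.approx(60.0, abs=1e-12)
        assert amount == pytest.approx(quantify.spot_capacity(), rel=0.02)

    def test_non_positive_arguments_rejected(self):
        with pytest.raises(ParameterError):
            quantify.spot_capacity(0.0, 1.0, 3.0)


class TestLod:
    def test_three_sigma_rule(self):
        m = quantify.fit_calibration([(0, 0.01), (1, 2.05), (2, 3.95),
                                      (3, 6.02)])
        assert m.lod_mM == pytest.approx(3 * m.residual_sd / m.slope, rel=1e-12)

    def test_parameter_recovery_and_no_false_detections(self, library, grid,
                                                        refs):
        # simulated films spanning 0-3.1 mM at default noise
        cal = synth.generate_calibration_series(
            [0, 0.5, 1, 1.5, 2, 2.5, 3], seed=31)
        model, _ = quantify.calibrate_spectra(cal)
        rng = np.random.default_rng(12)
        errs = []
        for i in range(60):
            c = rng.uniform(0.0, 3.1)
            spec = synth.SampleSpec(
                concentrations={"cystine": c},
                baseline_coeffs=tuple(rng.normal(0, 5e-4, 3)),
                noise_sd=synth.DEFAULT_NOISE_SD,
                vapour_factor=rng.uniform(0.05, 0.4),
                seed=synth.derived_seed(13, "film", i))
            film = synth.generate_sample(spec, library, grid)
            corrected, _ = preprocess.subtract_atmosphere(
                film, refs, include_water=False)
            resp = preprocess.cystine_response(
                preprocess.second_derivative(corrected))
            pred = quantify.predict_concentration(model, resp)
            errs.append(abs(pred.concentration_mM - c))
        assert np.median(errs) <= 0.1
        # triplicate blank films (the protocol's measurement unit) must
        # never cross the 3-sigma threshold
        for i in range(30):
            reps = []
            for rep in range(3):
                spec = synth.SampleSpec(
                    concentrations={"cystine": 0.0},
                    baseline_coeffs=tuple(rng.normal(0, 5e-4, 3)),
                    noise_sd=synth.DEFAULT_NOISE_SD,
                    vapour_factor=rng.uniform(0.05, 0.4),
                    seed=synth.derived_seed(14, "blank", i, rep))
                film = synth.generate_sample(spec, library, grid)
                corrected, _ = preprocess.subtract_atmosphere(
                    film, refs, include_water=False)
                resp = preprocess.cystine_response(
                    preprocess.second_derivative(corrected))
                reps.append(quantify.predict_concentration(
                    model, resp).concentration_mM)
            result = quantify.report_sample(
                f"blank{i}", reps, detection_threshold_mM=model.lod_mM)
            assert not result.detected
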