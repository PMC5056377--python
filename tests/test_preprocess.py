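"""Fractional subtraction and Savitzky-Golay second derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystir import preprocess, synth
from cystir.errors import DegenerateReferenceError, GridRangeError, ParameterError
from cystir.spectra import Spectrum, default_grid


def _flat_outside_window(grid, level=0.05):
    """A spectrum that is constant on the vapour fit window."""
    return Spectrum(grid, np.full(grid.size, level))


class TestFractionalSubtract:
    WINDOW = preprocess.VAPOUR_FIT_WINDOW

    def test_exact_construction(self, refs, grid):
        ref = refs["water_vapour"]
        base = np.full(grid.size, 0.0)          # flat on the fit window
        sample = Spectrum(grid, base + 0.3 * ref.absorbance)
        res = preprocess.fractional_subtract(sample, ref, self.WINDOW)
        assert res.factor == pytest.approx(0.3, abs=1e-9)
        np.testing.assert_allclose(res.corrected.absorbance, base, atol=1e-12)

    def test_orthogonal_sample_gives_zero_factor(self, grid):
        idx_ref = Spectrum(grid, np.zeros(grid.size))
        # reference non-zero only at even window indices, sample at odd ones
        w = idx_ref.window_indices(*self.WINDOW)
        ref_ab = np.zeros(grid.size)
        ref_ab[w[::2]] = 1.0
        sam_ab = np.zeros(grid.size)
        sam_ab[w[1::2]] = 1.0
        res = preprocess.fractional_subtract(Spectrum(grid, sam_ab),
                                             Spectrum(grid, ref_ab),
                                             self.WINDOW)
        assert res.factor == 0.0
        np.testing.assert_array_equal(res.corrected.absorbance, sam_ab)

    def test_zero_reference_on_window_rejected(self, grid):
        ref = Spectrum(grid, np.where(grid < 1500, 1.0, 0.0))
        sample = Spectrum(grid, np.ones(grid.size))
        with pytest.raises(DegenerateReferenceError):
            preprocess.fractional_subtract(sample, ref, self.WINDOW)

    def test_factor_matches_grid_search_oracle(self, refs, grid, rng):
        ref = refs["water_vapour"]
        sample = Spectrum(grid, 0.42 * ref.absorbance
                          + rng.normal(0, 1e-4, grid.size))
        res = preprocess.fractional_subtract(sample, ref, self.WINDOW)
        # brute-force 1-D grid search over the factor
        idx = sample.window_indices(*self.WINDOW)
        fs = np.linspace(0.0, 1.0, 2_000_001)
        s, r = sample.absorbance[idx], ref.absorbance[idx]
        sse = (np.sum(s * s) - 2 * fs * np.sum(s * r)
               + fs ** 2 * np.sum(r * r))
        best = fs[np.argmin(sse)]
        assert res.factor == pytest.approx(best, abs=1e-6)

    def test_closed_loop_with_simulator(self, library, grid, refs):
        spec = synth.SampleSpec(concentrations={}, vapour_factor=0.7,
                                noise_sd=0.0)
        s = synth.generate_sample(spec, library, grid)
        res = preprocess.fractional_subtract(s, refs["water_vapour"],
                                             self.WINDOW)
        assert res.factor == pytest.approx(0.7, abs=1e-6)


class TestSubtractAtmosphere:
    def test_recovers_both_factors_with_analytes_present(self, library, grid,
                                                         refs):
        spec = synth.SampleSpec(concentrations={"urea": 200.0,
                                                "creatinine": 10.0},
                                vapour_factor=0.25, water_factor=0.9,
                                noise_sd=0.0)
        s = synth.generate_sample(spec, library, grid)
        _, factors = preprocess.subtract_atmosphere(s, refs)
        assert factors["water_vapour"] == pytest.approx(0.25, abs=1e-6)
        assert factors["liquid_water"] == pytest.approx(0.9, abs=1e-6)

    def test_baseline_does_not_bias_factors(self, library, grid, refs):
        spec = synth.SampleSpec(concentrations={}, vapour_factor=0.2,
                                baseline_coeffs=(0.0, 1e-3, 5e-4),
                                noise_sd=0.0)
        s = synth.generate_sample(spec, library, grid)
        _, factors = preprocess.subtract_atmosphere(s, refs,
                                                    include_water=False)
        assert factors["water_vapour"] == pytest.approx(0.2, abs=1e-6)


class TestSecondDerivative:
    def test_constant_spectrum_gives_zero(self, grid):
        d2 = preprocess.second_derivative(Spectrum(grid, np.full(grid.size, 3.0)))
        np.testing.assert_allclose(d2.d2, 0.0, atol=1e-12)

    def test_quadratic_in_index_gives_constant_two(self, grid):
        i = np.arange(grid.size, dtype=float)
        d2 = preprocess.second_derivative(Spectrum(grid, i ** 2))
        np.testing.assert_allclose(d2.d2, 2.0, rtol=1e-9)

    def test_gaussian_band_minimum_at_centre(self, grid):
        band = synth.BandModel(1296.0, 1.0, 12.0, shape="gaussian")
        d2 = preprocess.second_derivative(Spectrum(grid, band.profile(grid)))
        i_min = int(np.argmin(d2.d2))
        assert abs(grid[i_min] - 1296.0) <= 2.0          # within 1 grid point

    def test_broad_gaussian_matches_analytic_derivative(self, grid):
        # for a band much wider than the filter window, SG approaches the
        # true second derivative (index units: x4 the per-cm^-1 value)
        fwhm, c = 100.0, 1500.0
        ab = np.exp(-4 * np.log(2) * ((grid - c) / fwhm) ** 2)
        d2 = preprocess.second_derivative(Spectrum(grid, ab))
        a = 4 * np.log(2) / fwhm ** 2
        analytic = 4 * (4 * a ** 2 * (grid - c) ** 2 - 2 * a) * ab
        dev = np.max(np.abs(d2.d2 - analytic)) / np.max(np.abs(analytic))
        assert dev < 0.02

    def test_linearity(self, grid, rng):
        s1 = Spectrum(grid, rng.normal(0, 1, grid.size))
        s2 = Spectrum(grid, rng.normal(0, 1, grid.size))
        combo = Spectrum(grid, 2.5 * s1.absorbance - 0.5 * s2.absorbance)
        d_combo = preprocess.second_derivative(combo).d2
        d_sep = (2.5 * preprocess.second_derivative(s1).d2
                 - 0.5 * preprocess.second_derivative(s2).d2)
        np.testing.assert_allclose(d_combo, d_sep, rtol=0, atol=1e-12)

    @pytest.mark.parametrize("window,poly,err", [
        (8, 3, "odd"), (9, 1, "polyorder"), (9, 9, "exceed"), (3001, 3, "fewer")])
    def test_parameter_validation(self, grid, window, poly, err):
        s = Spectrum(grid, np.zeros(grid.size))
        with pytest.raises(ParameterError, match=err):
            preprocess.second_derivative(s, window, poly)


class TestBandResponse:
    def test_zero_derivative_gives_zero(self, grid):
        d2 = preprocess.second_derivative(Spectrum(grid, np.zeros(grid.size)))
        assert preprocess.band_response(d2) == 0.0

    def test_doubling_concentration_doubles_response(self, library, grid):
        r = []
        for conc in (1.0, 2.0):
            s = synth.render_component(library["cystine"], grid, conc)
            r.append(preprocess.cystine_response(
                preprocess.second_derivative(s)))
        assert r[1] == pytest.approx(2 * r[0], abs=1e-9)

    def test_raw_response_is_negative_at_absorption_band(self, library, grid):
        s = synth.render_component(library["cystine"], grid, 1.0)
        d2 = preprocess.second_derivative(s)
        assert preprocess.band_response(d2) < 0
        assert preprocess.cystine_response(d2) == -preprocess.band_response(d2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(slope=st.floats(-1e-3, 1e-3), intercept=st.floats(-0.5, 0.5))
    def test_affine_baseline_invariance(self, slope, intercept, library):
        grid = default_grid()
        s = synth.render_component(library["cystine"], grid, 1.5)
        base = preprocess.cystine_response(preprocess.second_derivative(s))
        shifted = s.with_absorbance(s.absorbance + slope * grid + intercept)
        resp = preprocess.cystine_response(preprocess.second_derivative(shifted))
        assert resp == pytest.approx(base, abs=1e-9)

    def test_quadratic_baseline_cancels_in_difference(self, library, grid):
        s = synth.render_component(library["cystine"], grid, 1.5)
        base = preprocess.cystine_response(preprocess.second_derivative(s))
        t = np.linspace(-1, 1, grid.size)
        shifted = s.with_absorbance(s.absorbance + 0.01 * t ** 2)
        resp = preprocess.cystine_response(preprocess.second_derivative(shifted))
        assert resp == pytest.approx(base, abs=1e-9)

    def test_wavenumber_outside_coverage_raises(self, library):
        grid = default_grid(2000, 1400, 2)
        s = synth.render_component(library["urea"], grid, 1.0)
        d2 = preprocess.second_derivative(s)
        with pytest.raises(GridRangeError):
            preprocess.band_response(d2, 1296.0, 1280.0)
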