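"""Spectral preprocessing: fractional subtraction and second derivatives.

Atmospheric water-vapour lines and the liquid-water background are removed by
*fractional subtraction*: a reference spectrum is scaled by a least-squares
factor estimated on a fit window where the contaminant dominates, then
subtracted across the whole grid.  The factor is the closed-form projection

    f = <sample, reference> / <reference, reference>   (on the window)

i.e. the exact minimizer of sum (sample - f * reference)^2.

Second derivatives use a Savitzky-Golay filter (default window 9 points,
polynomial order 3, derivative with respect to grid *index*).  The derivative
annihilates baselines that are affine across the filter window, which is why
the cystine band response needs no separate baseline correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateReferenceError, ParameterError
from .spectra import ReferenceSet, Spectrum, nearest_index, resample_to_grid

#: Default fit windows (cm^-1).  Vapour lines are strong and sample features
#: weak in 2000-1800: the window deliberately stops above 1800 because the
#: urea/creatinine carbonyl-amide bands (1682-1705 cm^-1) reach well into
#: 1800-1700.  The liquid-water OH stretch dominates 3900-3100.
VAPOUR_FIT_WINDOW = (2000.0, 1800.0)
WATER_FIT_WINDOW = (3900.0, 3100.0)

#: Cystine second-derivative quantitation wavenumbers, cm^-1.
CYSTINE_BAND_A = 1296.0
CYSTINE_BAND_B = 1280.0

DEFAULT_SG_WINDOW = 9
DEFAULT_SG_POLYORDER = 3


@dataclass
class SubtractionResult:
    """Outcome of one fractional subtraction."""

    corrected: Spectrum
    factor: float
    fit_window: tuple[float, float]
    residual_rms: float


@dataclass
class DerivativeSpectrum:
    """Savitzky-Golay second derivative on the source grid.

    d2 is d^2A/di^2 in grid-index units (the convention is recorded in
    ``params`` so band responses are comparable across runs).
    """

    wavenumbers: np.ndarray
    d2: np.ndarray
    params: dict = field(default_factory=dict)

    def index_of(self, wn: float, tol: float = 1.0) -> int:
        return nearest_index(self.wavenumbers, wn, tol)


def fractional_subtract(sample: Spectrum, reference: Spectrum,
                        fit_window: tuple[float, float]) -> SubtractionResult:
    """Fit and subtract a scaled reference spectrum.

    The factor is estimated on `fit_window` only; the subtraction applies to
    the full common grid.  A reference that is numerically zero on the window
    raises :class:`DegenerateReferenceError`.
    """
    if not sample.same_grid(reference):
        reference = resample_to_grid(reference, sample.wavenumbers)
    idx = sample.window_indices(*fit_window)
    r = reference.absorbance[idx]
    s = sample.absorbance[idx]
    denom = float(np.dot(r, r))
    if denom <= 1e-30 * max(1.0, float(np.dot(s, s))):
        raise DegenerateReferenceError(
            f"reference is (numerically) zero on fit window {fit_window}")
    factor = float(np.dot(s, r) / denom)
    corrected = sample.with_absorbance(
        sample.absorbance - factor * reference.absorbance)
    residual = s - factor * r
    return SubtractionResult(
        corrected=corrected,
        factor=factor,
        fit_window=(float(fit_window[0]), float(fit_window[1])),
        residual_rms=float(np.sqrt(np.mean(residual ** 2))),
    )


def _trend_robust_factor(sample: Spectrum, reference: Spectrum,
                         fit_window: tuple[float, float]) -> float:
    """Reference scale fitted jointly with an affine trend on the window.

    Unlike the pure projection of :func:`fractional_subtract`, the factor is
    not biased by baseline drift across the fit window; only factor *
    reference is subtracted, never the trend.
    """
    idx = sample.window_indices(*fit_window)
    r = reference.absorbance[idx]
    s = sample.absorbance[idx]
    if float(np.dot(r, r)) <= 1e-30 * max(1.0, float(np.dot(s, s))):
        raise DegenerateReferenceError(
            f"reference is (numerically) zero on fit window {fit_window}")
    t = np.linspace(-1.0, 1.0, idx.size)
    design = np.column_stack([r, np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, s, rcond=None)
    return float(coef[0])


def subtract_atmosphere(sample: Spectrum, references: ReferenceSet,
                        vapour_window: tuple[float, float] = VAPOUR_FIT_WINDOW,
                        water_window: tuple[float, float] = WATER_FIT_WINDOW,
                        include_water: bool = True,
                        ) -> tuple[Spectrum, dict[str, float]]:
    """Remove water vapour, then (optionally) liquid water.

    Vapour is removed first because its lines contaminate the region where
    the liquid-water factor is estimated.  Because the liquid-water band
    tail in turn leaks into the vapour fit window, a single refinement pass
    re-fits the vapour factor after the water subtraction; the reported
    vapour factor is the sum of both passes.  For a sample that is exactly
    vapour + water on the fit windows this two-pass scheme recovers both
    factors exactly.  Returns the corrected spectrum and the fitted factors.
    """
    vap = references["water_vapour"]
    factors: dict[str, float] = {}
    f_vap = _trend_robust_factor(sample, vap, vapour_window)
    factors["water_vapour"] = f_vap
    corrected = sample.with_absorbance(
        sample.absorbance - f_vap * vap.absorbance)
    if include_water:
        wat = references["liquid_water"]
        f_wat = _trend_robust_factor(corrected, wat, water_window)
        factors["liquid_water"] = f_wat
        corrected = corrected.with_absorbance(
            corrected.absorbance - f_wat * wat.absorbance)
        refine = _trend_robust_factor(corrected, vap, vapour_window)
        factors["water_vapour"] += refine
        corrected = corrected.with_absorbance(
            corrected.absorbance - refine * vap.absorbance)
    return corrected, factors


def second_derivative(spectrum: Spectrum,
                      window_points: int = DEFAULT_SG_WINDOW,
                      polyorder: int = DEFAULT_SG_POLYORDER,
                      ) -> DerivativeSpectrum:
    """Savitzky-Golay second derivative (index units).

    A linear operator that reproduces polynomials up to `polyorder` exactly:
    a quadratic baseline differentiates to its exact (constant) second
    derivative, an affine baseline to zero.
    """
    if window_points % 2 == 0:
        raise ParameterError(f"window_points must be odd, got {window_points}")
    if polyorder < 2:
        raise ParameterError(
            f"polyorder must be >= 2 for a second derivative, got {polyorder}")
    if window_points <= polyorder:
        raise ParameterError(
            f"window_points ({window_points}) must exceed polyorder ({polyorder})")
    if len(spectrum) < window_points:
        raise ParameterError(
            f"spectrum has {len(spectrum)} points, fewer than the "
            f"{window_points}-point filter window")
    d2 = savgol_filter(spectrum.absorbance, window_points, polyorder,
                       deriv=2, delta=1.0)
    return DerivativeSpectrum(
        wavenumbers=spectrum.wavenumbers.copy(),
        d2=d2,
        params={"window_points": window_points, "polyorder": polyorder,
                "derivative_wrt": "grid index", "source_meta": dict(spectrum.meta)},
    )


def band_response(d2: DerivativeSpectrum,
                  wn_a: float = CYSTINE_BAND_A,
                  wn_b: float = CYSTINE_BAND_B) -> float:
    """Second-derivative intensity difference d2(wn_a) - d2(wn_b).

    The default pair (1296, 1280 cm^-1) targets the cystine band: at an
    absorption maximum the second derivative is negative, so this raw
    difference is negative for increasing cystine.  Quantitation uses the
    negated value (see :func:`cystine_response`) so calibration slopes are
    positive.  Wavenumbers snap to the nearest grid point within +/-1 cm^-1.
    """
    ia = d2.index_of(wn_a)
    ib = d2.index_of(wn_b)
    return float(d2.d2[ia] - d2.d2[ib])


def cystine_response(d2: DerivativeSpectrum,
                     wn_a: float = CYSTINE_BAND_A,
                     wn_b: float = CYSTINE_BAND_B) -> float:
    """Positive-going cystine band depth: -(d2(1296) - d2(1280))."""
    return -band_response(d2, wn_a, wn_b)
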