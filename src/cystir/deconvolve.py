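"""Urea/creatinine quantitation by constrained spectral deconvolution.

The 1510-1445 cm^-1 region of an undried urine absorbance spectrum is
modelled as a non-negative combination of pure-component reference spectra
plus a low-order polynomial baseline:

    sample(w) ~ sum_c  coef_c * ref_c(w)  +  baseline(w),   coef_c >= 0

solved as a bounded linear least-squares problem (component coefficients
constrained to [0, inf), baseline coefficients free).  Concentrations follow
from the coefficients via the concentration at which each reference was
measured (Beer-Lambert linearity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .errors import ConditioningError, GridRangeError, ParameterError
from .spectra import ReferenceSet, Spectrum

#: Default quantitation window, cm^-1 (inclusive endpoints, nearest-grid).
DEFAULT_WINDOW = (1510.0, 1445.0)
DEFAULT_BASELINE_ORDER = 1

_MAX_CONDITION = 1e8


@dataclass
class DeconvolutionFit:
    """Result of a windowed non-negative component fit."""

    coefficients: dict[str, float]           # >= 0, per component
    baseline_coeffs: np.ndarray              # highest order first
    window: tuple[float, float]
    residual_rms: float
    concentrations: dict[str, float] = field(default_factory=dict)


def _baseline_design(n: int, order: int) -> np.ndarray:
    """Polynomial columns on a [-1, 1] coordinate (well conditioned)."""
    t = np.linspace(-1.0, 1.0, n)
    return np.column_stack([t ** k for k in range(order + 1)])


def fit_components(sample: Spectrum, references: ReferenceSet,
                   window: tuple[float, float] = DEFAULT_WINDOW,
                   baseline_order: int = DEFAULT_BASELINE_ORDER,
                   components: Sequence[str] = ("urea", "creatinine"),
                   ) -> DeconvolutionFit:
    """Fit non-negative component scales plus a free polynomial baseline.

    Requires at least twice as many grid points inside the window as free
    parameters; collinear references raise :class:`ConditioningError` with
    the offending condition number.
    """
    if baseline_order < 0:
        raise ParameterError(f"baseline_order must be >= 0, got {baseline_order}")
    for name in components:
        references[name]                     # KeyError early if missing
    if not sample.same_grid(references[components[0]]):
        raise GridRangeError(
            "sample and references must share one grid; resample first")
    idx = sample.window_indices(*window)
    n_free = len(components) + baseline_order + 1
    if idx.size < 2 * n_free:
        raise ParameterError(
            f"window {window} has {idx.size} points, need >= {2 * n_free} "
            f"for {n_free} free parameters")
    ref_cols = np.column_stack(
        [references[name].absorbance[idx] for name in components])
    base_cols = _baseline_design(idx.size, baseline_order)
    # scale columns to unit norm for conditioning; undo on the way out
    design = np.hstack([ref_cols, base_cols])
    norms = np.linalg.norm(design, axis=0)
    if np.any(norms == 0):
        raise ConditioningError("design matrix has an identically-zero column")
    scaled = design / norms
    cond = float(np.linalg.cond(scaled))
    if cond > _MAX_CONDITION:
        raise ConditioningError(
            f"references are (near-)collinear on window {window}: "
            f"condition number {cond:.3g} exceeds {_MAX_CONDITION:.0e}")
    y = sample.absorbance[idx]
    # unconstrained solve is exact; only fall back to the bounded solver
    # when a component coefficient actually violates non-negativity
    coef_scaled, *_ = np.linalg.lstsq(scaled, y, rcond=None)
    tol_neg = 1e-10 * max(1.0, float(np.max(np.abs(coef_scaled))))
    if np.any(coef_scaled[:len(components)] < -tol_neg):
        lower = np.concatenate([np.zeros(len(components)),
                                np.full(baseline_order + 1, -np.inf)])
        upper = np.full(n_free, np.inf)
        sol = lsq_linear(scaled, y, bounds=(lower, upper), tol=1e-14)
        coef_scaled = sol.x
    coef = coef_scaled / norms
    residual = y - design @ coef
    return DeconvolutionFit(
        coefficients={name: float(max(0.0, c))
                      for name, c in zip(components, coef)},
        baseline_coeffs=coef[len(components):][::-1].copy(),
        window=(float(window[0]), float(window[1])),
        residual_rms=float(np.sqrt(np.mean(residual ** 2))),
    )


def concentration_from_coefficients(
        coefficients: Mapping[str, float],
        component_calibrations: Mapping[str, float]) -> dict[str, float]:
    """Map fitted reference scales to concentrations (mM).

    `component_calibrations[name]` is the concentration at which that
    reference spectrum was measured (mM per unit coefficient), so
    concentration = coefficient * calibration slope.  Non-negativity is
    preserved.  Missing calibrations raise a configuration error.
    """
    missing = [n for n in coefficients if n not in component_calibrations]
    if missing:
        raise ParameterError(
            f"no calibration available for fitted components: {missing}")
    return {name: float(max(0.0, c) * component_calibrations[name])
            for name, c in coefficients.items()}


def quantify_urine(sample: Spectrum, references: ReferenceSet,
                   component_calibrations: Mapping[str, float],
                   window: tuple[float, float] = DEFAULT_WINDOW,
                   baseline_order: int = DEFAULT_BASELINE_ORDER,
                   components: Sequence[str] = ("urea", "creatinine"),
                   ) -> DeconvolutionFit:
    """fit_components + concentration mapping in one call."""
    fit = fit_components(sample, references, window, baseline_order, components)
    fit.concentrations = concentration_from_coefficients(
        fit.coefficients, component_calibrations)
    return fit
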