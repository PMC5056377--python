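"""Cystine calibration, prediction, bookkeeping and reporting conventions.

Calibration is a straight line through the origin (no error weighting) from
second-derivative band response to cystine concentration:

    slope = sum(c_i * r_i) / sum(c_i^2)

Reporting conventions for clinical comparability:

* the protocol measures *insoluble* cystine; the clinical comparator (IEC)
  reports total cystine, so detected samples get a +1.0 mM offset (the
  cystine solubility limit) when expressed as total cystine;
* samples with no detectable insoluble cystine are censored to the interval
  0.5 +/- 0.5 mM of total cystine (somewhere below the solubility limit);
* dilution bookkeeping follows the centrifugation protocol (1 mL urine
  pelleted, resuspended in 1 mL water: a 1:1 identity by default);
* the dilution-robust severity measure is the cystine:creatinine ratio in
  uM cystine per mM creatinine.

The spot-capacity check converts the evanescent-wave active volume (a film
~1 um high over a 3 mm spot) into the nanomoles of cystine it can hold,
given the cystine molecular volume of 193 A^3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.constants import Avogadro

from .errors import CalibrationError, ParameterError
from .preprocess import (
    DEFAULT_SG_POLYORDER,
    DEFAULT_SG_WINDOW,
    cystine_response,
    second_derivative,
)
from .spectra import Spectrum

#: Cystine solubility limit in urine, mM: the offset added to insoluble
#: cystine when comparing against total-cystine assays.
SOLUBILITY_OFFSET_MM = 1.0

#: Censoring convention for undetected samples: total cystine reported as
#: centre +/- half-width (mM).
CENSORED_CENTRE_MM = 0.5
CENSORED_HALFWIDTH_MM = 0.5

#: Default limit-of-detection multiplier (3-sigma rule).
LOD_SIGMA = 3.0


@dataclass
class CalibrationModel:
    """Through-origin linear calibration: response = slope * concentration."""

    slope: float                      # response units per mM
    n_points: int
    r_squared: float
    residual_sd: float                # response units
    concentration_range: tuple[float, float]
    warnings: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def lod_mM(self) -> float:
        """3-sigma limit of detection, mM (inf for an unusable slope)."""
        if self.slope <= 0:
            return math.inf
        return LOD_SIGMA * self.residual_sd / self.slope

    # -- JSON round-trip ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "slope": self.slope,
            "n_points": self.n_points,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "concentration_range": list(self.concentration_range),
            "warnings": self.warnings,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and "\n" not in source
                                        and Path(source).exists()):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(slope=d["slope"], n_points=d["n_points"],
                   r_squared=d["r_squared"], residual_sd=d["residual_sd"],
                   concentration_range=tuple(d["concentration_range"]),
                   warnings=list(d.get("warnings", [])),
                   meta=dict(d.get("meta", {})))


@dataclass
class Prediction:
    """A predicted concentration with extrapolation flag."""

    concentration_mM: float
    extrapolated: bool = False

    def __float__(self) -> float:
        return self.concentration_mM


@dataclass
class QuantResult:
    """Per-sample quantitation summary (mirrors the per-sample report rows)."""

    sample_id: str
    replicate_mM: tuple[float, ...]
    insoluble_cystine_mM: float     # 0.0 when not detected
    sem_mM: float
    detected: bool
    total_cystine_mM: float         # insoluble + offset, or censored centre
    censored: bool                  # True -> total is the 0.5 +/- 0.5 interval
    censored_halfwidth_mM: float
    creatinine_mM: float | None = None
    urea_mM: float | None = None
    ratio_uM_per_mM: float | None = None
    ratio_undefined: bool = False
    extrapolated: bool = False


def fit_calibration(series: Sequence[tuple[float, float]],
                    meta: Mapping | None = None) -> CalibrationModel:
    """Through-origin ordinary least squares on (concentration, response).

    No error weighting.  Needs at least two points spanning a non-zero
    concentration range; an all-zero concentration series is degenerate.
    A negative fitted slope is flagged as a warning, not an error.
    """
    if len(series) < 2:
        raise CalibrationError(
            f"calibration needs >= 2 points, got {len(series)}")
    conc = np.asarray([c for c, _ in series], dtype=float)
    resp = np.asarray([r for _, r in series], dtype=float)
    if np.any(conc < 0):
        raise CalibrationError("calibration concentrations must be >= 0")
    denom = float(np.sum(conc ** 2))
    if denom == 0.0:
        raise CalibrationError(
            "degenerate calibration: all concentrations are zero")
    slope = float(np.sum(conc * resp) / denom)
    residuals = resp - slope * conc
    ss_res = float(np.sum(residuals ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    residual_sd = math.sqrt(ss_res / (len(series) - 1))
    warnings = []
    if slope <= 0:
        warnings.append(f"non-positive calibration slope ({slope:.3g}); "
                        "model unusable for prediction")
    return CalibrationModel(
        slope=slope,
        n_points=len(series),
        r_squared=r_squared,
        residual_sd=residual_sd,
        concentration_range=(float(conc.min()), float(conc.max())),
        warnings=warnings,
        meta=dict(meta or {}),
    )


def calibrate_spectra(series: Sequence[tuple[float, Spectrum]],
                      window_points: int = DEFAULT_SG_WINDOW,
                      polyorder: int = DEFAULT_SG_POLYORDER,
                      ) -> tuple[CalibrationModel, list[float]]:
    """Fit a calibration directly from (concentration, spectrum) standards.

    Each standard is converted to its second-derivative cystine band
    response; the filter parameters are recorded in the model metadata.
    """
    responses = [cystine_response(second_derivative(s, window_points, polyorder))
                 for _, s in series]
    pairs = [(c, r) for (c, _), r in zip(series, responses)]
    model = fit_calibration(pairs, meta={
        "sg_window_points": window_points,
        "sg_polyorder": polyorder,
        "response": "-(d2[1296] - d2[1280]) cm^-1, index-unit derivative",
    })
    return model, responses


def predict_concentration(model: CalibrationModel, response: float) -> Prediction:
    """Invert the calibration: concentration = response / slope, >= 0.

    Responses above the calibrated range give a flagged (not rejected)
    extrapolation; non-positive responses clip to 0 mM.
    """
    if model.slope <= 0:
        raise CalibrationError(
            f"cannot predict from a model with slope {model.slope:.3g} <= 0")
    conc = max(0.0, float(response) / model.slope)
    extrapolated = conc > model.concentration_range[1]
    return Prediction(concentration_mM=conc, extrapolated=extrapolated)


def apply_dilution(concentration_in_film: float, original_volume_mL: float,
                   resuspension_volume_mL: float) -> float:
    """Concentration in the original urine from the measured film.

    The pellet from `original_volume_mL` of urine is resuspended in
    `resuspension_volume_mL` of water; the study protocol (1 mL -> 1 mL) is
    the identity.
    """
    if original_volume_mL <= 0 or resuspension_volume_mL <= 0:
        raise ParameterError(
            f"volumes must be > 0, got {original_volume_mL} mL -> "
            f"{resuspension_volume_mL} mL")
    return concentration_in_film * (resuspension_volume_mL / original_volume_mL)


def report_sample(sample_id: str,
                  insoluble_replicates_mM: Sequence[float],
                  creatinine_mM: float | None = None,
                  urea_mM: float | None = None,
                  detection_threshold_mM: float = 0.0,
                  extrapolated: bool = False) -> QuantResult:
    """Summarize replicates and apply the reporting conventions.

    Mean and standard error over replicates (n-1 sd; SEM is 0 for a single
    replicate); detection is mean > threshold.  Undetected samples report
    insoluble cystine as 0 and total cystine as the censored 0.5 +/- 0.5 mM
    interval; detected samples get the +1 mM solubility offset.  The ratio is
    uM cystine per mM creatinine and is undefined (flagged, not an error)
    when creatinine is missing or <= 0.
    """
    reps = tuple(float(x) for x in insoluble_replicates_mM)
    if not reps:
        raise ParameterError(f"sample {sample_id!r}: at least 1 replicate required")
    mean = float(np.mean(reps))
    sem = float(np.std(reps, ddof=1) / math.sqrt(len(reps))) if len(reps) > 1 else 0.0
    detected = mean > detection_threshold_mM
    if detected:
        insoluble = mean
        total = mean + SOLUBILITY_OFFSET_MM
        censored = False
        halfwidth = 0.0
    else:
        insoluble = 0.0
        total = CENSORED_CENTRE_MM
        censored = True
        halfwidth = CENSORED_HALFWIDTH_MM
    ratio: float | None
    if creatinine_mM is None or creatinine_mM <= 0:
        ratio = None
        ratio_undefined = True
    else:
        ratio = insoluble * 1000.0 / creatinine_mM
        ratio_undefined = False
    return QuantResult(
        sample_id=sample_id,
        replicate_mM=reps,
        insoluble_cystine_mM=insoluble,
        sem_mM=sem,
        detected=detected,
        total_cystine_mM=total,
        censored=censored,
        censored_halfwidth_mM=halfwidth,
        creatinine_mM=creatinine_mM,
        urea_mM=urea_mM,
        ratio_uM_per_mM=ratio,
        ratio_undefined=ratio_undefined,
        extrapolated=extrapolated,
    )


def spot_capacity(molecular_volume_A3: float = 193.0,
                  film_height_um: float = 1.0,
                  spot_diameter_mm: float = 3.0) -> float:
    """Nanomoles of analyte that fit in the active spectroscopic volume.

    The evanescent wave probes a cylindrical film of the given height over
    the measurement spot; dividing that volume by the molecular volume and
    Avogadro's number gives the capacity in nmol.  With cystine's molecular
    volume of 193 A^3, a ~1 um film over a 3 mm spot holds ~60 nmol.
    """
    if molecular_volume_A3 <= 0 or film_height_um <= 0 or spot_diameter_mm <= 0:
        raise ParameterError("spot_capacity arguments must all be > 0")
    radius_m = 0.5 * spot_diameter_mm * 1e-3
    height_m = film_height_um * 1e-6
    volume_m3 = math.pi * radius_m ** 2 * height_m
    molecular_volume_m3 = molecular_volume_A3 * 1e-30
    moles = volume_m3 / molecular_volume_m3 / Avogadro
    return moles * 1e9


def aliquot_amount_nmol(volume_uL: float, concentration_mM: float) -> float:
    """Nanomoles in a dried aliquot: uL x mM = nmol."""
    if volume_uL <= 0:
        raise ParameterError(f"aliquot volume must be > 0, got {volume_uL}")
    if concentration_mM < 0:
        raise ParameterError(
            f"concentration must be >= 0, got {concentration_mM}")
    return volume_uL * concentration_mM
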