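"""Forward simulation of ATR-FTIR spectra and comparator assays.

Emulates the study conditions the analysis modules assume: dried cystine
calibration films (0-3 mM, 5 uL aliquots), undried urine spectra dominated by
urea and creatinine in the 1510-1445 cm^-1 region, dried insoluble-fraction
films, water-vapour line contamination, liquid-water background, polynomial
baseline drift, Gaussian detector noise, and noisy clinical comparators
(Jaffe creatinine with a positive bias, ion-exchange-chromatography total
cystine = soluble + insoluble).

Band positions for cystine (1296, 845, 775 cm^-1) and the urea/creatinine
overlap inside 1510-1445 cm^-1 follow the real compounds; the molar response
values themselves are synthetic placeholders chosen to give realistic
signal-to-noise, since true molar absorptivities at these wavenumbers are not
tabulated here.  Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .spectra import ReferenceSet, Spectrum, default_grid, write_spectrum

#: Default detector noise, absorbance units (RMS, i.i.d. per grid point).
DEFAULT_NOISE_SD = 2e-4

#: Default dried-aliquot volume (uL) and evanescent-volume capacity (nmol).
DEFAULT_ALIQUOT_UL = 5.0
DEFAULT_CAPACITY_NMOL = 60.0

#: Cystine solubility limit in urine, mM.
SOLUBILITY_LIMIT_MM = 1.0

_FOUR_LN2 = 4.0 * math.log(2.0)


# ---------------------------------------------------------------------------
# Band and component models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandModel:
    """One absorbance band: peak-normalized profile times a molar height.

    height is the absorbance per mM at the band maximum; fwhm is the full
    width at half maximum in cm^-1.
    """

    center: float
    height: float
    fwhm: float
    shape: str = "pseudo_voigt"
    eta: float = 0.5          # Lorentzian fraction for pseudo_voigt

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ParameterError(f"band fwhm must be > 0, got {self.fwhm}")
        if self.height < 0:
            raise ParameterError(f"band height must be >= 0, got {self.height}")
        if not 0.0 <= self.eta <= 1.0:
            raise ParameterError(f"eta must be in [0, 1], got {self.eta}")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ParameterError(f"unknown band shape {self.shape!r}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Peak-normalized band profile on `grid`."""
        x = np.asarray(grid, float) - self.center
        g = np.exp(-_FOUR_LN2 * (x / self.fwhm) ** 2)
        if self.shape == "gaussian":
            return g
        lor = 1.0 / (1.0 + 4.0 * (x / self.fwhm) ** 2)
        if self.shape == "lorentzian":
            return lor
        return self.eta * lor + (1.0 - self.eta) * g


@dataclass(frozen=True)
class ComponentModel:
    """A named component as a sum of bands."""

    name: str
    bands: tuple[BandModel, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ParameterError(f"component {self.name!r} needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))


def _vapour_bands() -> tuple[BandModel, ...]:
    """A comb of 40 narrow Lorentzian lines across 2000-1300 cm^-1.

    Line heights vary deterministically so the comb has the irregular look of
    rovibrational water lines; no line falls within 20 cm^-1 of the 1296/1280
    cystine analysis points.
    """
    centers = np.linspace(2000.0, 1300.0, 42)[1:-1]
    rng = np.random.default_rng(712_025)          # fixed: part of the model
    heights = 0.02 * (0.4 + 0.6 * rng.random(centers.size))
    return tuple(BandModel(float(c), float(h), 4.0, shape="lorentzian")
                 for c, h in zip(centers, heights))


def default_component_library() -> dict[str, ComponentModel]:
    """Synthetic component band library used throughout the package.

    cystine bands sit at 1296, 845 and 775 cm^-1; urea and creatinine have
    distinct overlapping bands inside the 1510-1445 cm^-1 quantitation window;
    liquid water contributes the broad OH-stretch (~3400 cm^-1) and HOH-bend
    (~1640 cm^-1) bands; water vapour is a comb of narrow lines.
    """
    return {
        "cystine": ComponentModel("cystine", (
            BandModel(1296.0, 0.035, 12.0),
            BandModel(845.0, 0.012, 14.0),
            BandModel(775.0, 0.010, 12.0),
        )),
        "urea": ComponentModel("urea", (
            BandModel(1682.0, 0.0040, 45.0, shape="gaussian"),
            BandModel(1627.0, 0.0030, 40.0, shape="gaussian"),
            BandModel(1465.0, 0.0015, 30.0, shape="gaussian"),
        )),
        "creatinine": ComponentModel("creatinine", (
            BandModel(1705.0, 0.0030, 30.0, shape="gaussian"),
            BandModel(1493.0, 0.0040, 20.0, shape="gaussian"),
            BandModel(1418.0, 0.0020, 22.0, shape="gaussian"),
        )),
        "liquid_water": ComponentModel("liquid_water", (
            BandModel(3400.0, 0.60, 350.0, shape="gaussian"),
            BandModel(1640.0, 0.50, 60.0, shape="gaussian"),
        )),
        "water_vapour": ComponentModel("water_vapour", _vapour_bands()),
    }


def library_from_config(config: Mapping) -> dict[str, ComponentModel]:
    """Build a component library from a parsed YAML/JSON mapping.

    Expected structure::

        components:
          cystine:
            bands:
              - {center: 1296, height: 0.02, fwhm: 12, shape: pseudo_voigt}
    """
    out: dict[str, ComponentModel] = {}
    for name, spec in config["components"].items():
        bands = tuple(BandModel(**b) for b in spec["bands"])
        out[name] = ComponentModel(name, bands)
    return out


def reference_set_from_library(library: Mapping[str, ComponentModel] | None = None,
                               grid: np.ndarray | None = None) -> ReferenceSet:
    """Render each library component at unit amount (1 mM / unit factor)."""
    library = default_component_library() if library is None else dict(library)
    grid = default_grid() if grid is None else np.asarray(grid, float)
    comps = {name: render_component(model, grid, 1.0)
             for name, model in library.items()}
    return ReferenceSet(comps)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_component(component: ComponentModel, grid: np.ndarray,
                     concentration: float) -> Spectrum:
    """Beer-Lambert rendering: absorbance = concentration x sum of bands.

    Exactly linear in concentration (saturation is modelled separately by
    :func:`saturate_film`).
    """
    if concentration < 0:
        raise ParameterError(
            f"concentration must be >= 0, got {concentration}")
    grid = np.asarray(grid, float)
    ab = np.zeros_like(grid)
    for band in component.bands:
        ab += band.height * band.profile(grid)
    return Spectrum(grid.copy(), concentration * ab,
                    {"component": component.name,
                     "concentration_mM": concentration})


def saturate_film(spectrum: Spectrum, amount_nmol: float,
                  capacity_nmol: float) -> Spectrum:
    """Scale a rendered film spectrum by the evanescent-volume limit.

    The probed layer holds at most `capacity_nmol`; response is linear below
    capacity and plateaus above it: scale = min(1, capacity/amount).
    """
    if capacity_nmol <= 0:
        raise ParameterError(f"capacity must be > 0, got {capacity_nmol}")
    if amount_nmol < 0:
        raise ParameterError(f"amount must be >= 0, got {amount_nmol}")
    scale = 1.0 if amount_nmol <= capacity_nmol else capacity_nmol / amount_nmol
    return spectrum.with_absorbance(spectrum.absorbance * scale,
                                    saturation_scale=scale)


# ---------------------------------------------------------------------------
# Sample generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSpec:
    """Everything needed to simulate one measured spectrum, reproducibly."""

    concentrations: Mapping[str, float] = field(default_factory=dict)
    baseline_coeffs: tuple[float, ...] = ()    # polyval coeffs on t in [-1, 1]
    noise_sd: float = DEFAULT_NOISE_SD
    vapour_factor: float = 0.0
    water_factor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ParameterError(f"negative concentration for {name!r}: {c}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")


def generate_sample(spec: SampleSpec,
                    library: Mapping[str, ComponentModel] | None = None,
                    grid: np.ndarray | None = None) -> Spectrum:
    """Simulate one spectrum: components + water + vapour + baseline + noise."""
    library = default_component_library() if library is None else library
    grid = default_grid() if grid is None else np.asarray(grid, float)
    ab = np.zeros_like(grid)
    for name, conc in spec.concentrations.items():
        if name not in library:
            raise KeyError(f"unknown component {name!r}; library has "
                           f"{sorted(library)}")
        ab += render_component(library[name], grid, conc).absorbance
    if spec.water_factor:
        ab += spec.water_factor * render_component(
            library["liquid_water"], grid, 1.0).absorbance
    if spec.vapour_factor:
        ab += spec.vapour_factor * render_component(
            library["water_vapour"], grid, 1.0).absorbance
    if spec.baseline_coeffs:
        t = _unit_interval(grid)
        ab += np.polyval(spec.baseline_coeffs, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ab = ab + rng.normal(0.0, spec.noise_sd, grid.size)
    return Spectrum(grid.copy(), ab, {
        "simulated": "true",
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
    })


def _unit_interval(grid: np.ndarray) -> np.ndarray:
    mid = 0.5 * (grid[0] + grid[-1])
    half = 0.5 * abs(grid[0] - grid[-1])
    return (grid - mid) / half


def derived_seed(master: int, *parts) -> int:
    """Stable sub-seed from a master seed and identifying parts (< 2^31)."""
    key = repr((int(master),) + tuple(parts)).encode()
    h = hashlib.blake2s(key, digest_size=4).digest()
    return int.from_bytes(h, "little") % (2 ** 31)


def generate_calibration_series(
    concentrations: Sequence[float],
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    library: Mapping[str, ComponentModel] | None = None,
    grid: np.ndarray | None = None,
    aliquot_uL: float = DEFAULT_ALIQUOT_UL,
    capacity_nmol: float = DEFAULT_CAPACITY_NMOL,
    baseline_scale: float = 5e-4,
    replicates: int = 3,
) -> list[tuple[float, Spectrum]]:
    """Dried-film cystine calibration standards (default series 0-3 mM).

    Each standard is dried and measured `replicates` times (the protocol
    measures films in triplicate), giving the calibration residual a stable
    noise estimate for the limit-of-detection rule.  Standards are clean
    aqueous cystine films: quadratic baseline drift and detector noise are
    included, atmospheric contamination is not (standards are recorded under
    dry-air purge).  The film saturates only above the evanescent-volume
    capacity, which a 0-3 mM series at 5 uL never reaches.
    """
    if len(concentrations) == 0:
        raise ParameterError("calibration series needs at least one concentration")
    if any(c < 0 for c in concentrations):
        raise ParameterError("calibration concentrations must be >= 0")
    if replicates < 1:
        raise ParameterError(f"replicates must be >= 1, got {replicates}")
    library = default_component_library() if library is None else library
    grid = default_grid() if grid is None else np.asarray(grid, float)
    series: list[tuple[float, Spectrum]] = []
    for i, conc in enumerate(concentrations):
        for rep in range(replicates):
            sub = derived_seed(seed, "calibration", i, rep)
            rng = np.random.default_rng(
                derived_seed(seed, "calibration-baseline", i, rep))
            baseline = (tuple(rng.normal(0.0, baseline_scale, 3))
                        if baseline_scale else ())
            rendered = render_component(library["cystine"], grid, conc)
            rendered = saturate_film(rendered, conc * aliquot_uL, capacity_nmol)
            noise_spec = SampleSpec(concentrations={}, baseline_coeffs=baseline,
                                    noise_sd=noise_sd, seed=sub)
            extras = generate_sample(noise_spec, library, grid)
            s = rendered.with_absorbance(rendered.absorbance + extras.absorbance,
                                         standard_mM=conc, replicate=rep)
            series.append((float(conc), s))
    return series


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDistributions:
    """Parameter block for cohort simulation (all concentrations in mM)."""

    urea_range: tuple[float, float] = (28.0, 443.0)
    creatinine_range: tuple[float, float] = (1.0, 20.0)
    cystine_range: tuple[float, float] = (0.1, 3.1)
    p_patient_zero_cystine: float = 5.0 / 22.0
    soluble_cystine_patient: tuple[float, float] = (0.5, 1.0)
    soluble_cystine_control: tuple[float, float] = (0.05, 0.3)
    jaffe_bias_mM: float = 1.4
    jaffe_sd_mM: float = 1.0
    iec_sd_mM: float = 0.1
    vapour_range: tuple[float, float] = (0.05, 0.4)
    water_factor_urine: float = 1.0
    baseline_scale: float = 5e-4
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("urea_range", "creatinine_range", "cystine_range",
                     "soluble_cystine_patient", "soluble_cystine_control",
                     "vapour_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ParameterError(f"invalid {name}: ({lo}, {hi})")
        if not 0.0 <= self.p_patient_zero_cystine <= 1.0:
            raise ParameterError("p_patient_zero_cystine must be in [0, 1]")
        if self.noise_sd < 0 or self.jaffe_sd_mM < 0 or self.iec_sd_mM < 0:
            raise ParameterError("noise parameters must be >= 0")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


@dataclass
class CohortSample:
    """Simulated spectra for one subject."""

    sample_id: str
    urine_spectrum: Spectrum                 # undried, as-collected
    insoluble_replicates: list[Spectrum]     # dried films of the pellet


@dataclass
class CohortTruth:
    """Ground truth and comparator values for a simulated cohort."""

    table: pd.DataFrame          # one row per sample
    error_model: dict            # recorded comparator error parameters

    def __eq__(self, other) -> bool:          # convenience for determinism tests
        return (isinstance(other, CohortTruth)
                and self.table.equals(other.table)
                and self.error_model == other.error_model)


def generate_cohort(
    n_patients: int,
    n_controls: int,
    distributions: CohortDistributions | Mapping | None = None,
    seed: int = 0,
    library: Mapping[str, ComponentModel] | None = None,
    grid: np.ndarray | None = None,
) -> tuple[list[CohortSample], CohortTruth]:
    """Simulate a cohort of cystinuric patients plus healthy controls.

    Per subject: one undried-urine spectrum (urea + creatinine + water),
    `n_replicates` dried insoluble-fraction films (cystine only for patients,
    none for controls), and paired comparator assays (Jaffe creatinine with a
    constant positive bias, IEC total cystine = soluble + insoluble).
    """
    if n_patients < 0 or n_controls < 0:
        raise ParameterError("cohort counts must be >= 0")
    if distributions is None:
        dist = CohortDistributions()
    elif isinstance(distributions, CohortDistributions):
        dist = distributions
    else:
        dist = CohortDistributions(**dict(distributions))
    library = default_component_library() if library is None else library
    grid = default_grid() if grid is None else np.asarray(grid, float)

    samples: list[CohortSample] = []
    rows: list[dict] = []
    ids = ([f"P{i + 1}" for i in range(n_patients)]
           + [f"N{i + 1}" for i in range(n_controls)])
    for sid in ids:
        is_patient = sid.startswith("P")
        rng = np.random.default_rng(derived_seed(seed, "truth", sid))
        urea = rng.uniform(*dist.urea_range)
        creat = rng.uniform(*dist.creatinine_range)
        if is_patient:
            zero = rng.random() < dist.p_patient_zero_cystine
            cystine = 0.0 if zero else rng.uniform(*dist.cystine_range)
            # a sample with insoluble cystine is saturated: its soluble
            # fraction sits at the ~1 mM solubility limit
            soluble = (SOLUBILITY_LIMIT_MM if cystine > 0
                       else rng.uniform(*dist.soluble_cystine_patient))
            treated = rng.random() < (0.8 if zero else 0.35)
        else:
            cystine = 0.0
            soluble = rng.uniform(*dist.soluble_cystine_control)
            treated = False
        jaffe = creat + dist.jaffe_bias_mM + rng.normal(0.0, dist.jaffe_sd_mM)
        iec = max(0.0, cystine + soluble + rng.normal(0.0, dist.iec_sd_mM))
        vapour = rng.uniform(*dist.vapour_range)

        urine_spec = SampleSpec(
            concentrations={"urea": urea, "creatinine": creat},
            baseline_coeffs=tuple(rng.normal(0.0, dist.baseline_scale, 3)),
            noise_sd=dist.noise_sd,
            vapour_factor=vapour,
            water_factor=dist.water_factor_urine,
            seed=derived_seed(seed, "urine", sid),
        )
        urine = generate_sample(urine_spec, library, grid)
        urine.meta["sample_id"] = sid

        reps: list[Spectrum] = []
        for r in range(dist.n_replicates):
            rrng = np.random.default_rng(derived_seed(seed, "film-base", sid, r))
            film_spec = SampleSpec(
                concentrations={"cystine": cystine},
                baseline_coeffs=tuple(rrng.normal(0.0, dist.baseline_scale, 3)),
                noise_sd=dist.noise_sd,
                vapour_factor=rrng.uniform(*dist.vapour_range),
                water_factor=0.0,
                seed=derived_seed(seed, "film", sid, r),
            )
            film = generate_sample(film_spec, library, grid)
            film.meta.update(sample_id=sid, replicate=r)
            reps.append(film)

        samples.append(CohortSample(sid, urine, reps))
        rows.append({
            "sample_id": sid,
            "group": "patient" if is_patient else "control",
            "treated": treated,
            "insoluble_cystine_mM": cystine,
            "soluble_cystine_mM": soluble,
            "creatinine_mM": creat,
            "urea_mM": urea,
            "jaffe_creatinine_mM": jaffe,
            "iec_total_cystine_mM": iec,
        })

    truth = CohortTruth(
        table=pd.DataFrame(rows),
        error_model={
            "jaffe": {"bias_mM": dist.jaffe_bias_mM, "sd_mM": dist.jaffe_sd_mM},
            "iec": {"bias_mM": 0.0, "sd_mM": dist.iec_sd_mM,
                    "reports": "total = soluble + insoluble"},
            "seed": int(seed),
        },
    )
    return samples, truth


def save_cohort(samples: list[CohortSample], truth: CohortTruth,
                directory: str | Path) -> None:
    """Write a cohort as CSV spectra + truth.csv + manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "cystir-cohort/1", "samples": {}}
    for s in samples:
        entry = {"urine": f"{s.sample_id}_urine.csv", "replicates": []}
        write_spectrum(s.urine_spectrum, directory / entry["urine"])
        for r, spec in enumerate(s.insoluble_replicates):
            fname = f"{s.sample_id}_film{r}.csv"
            write_spectrum(spec, directory / fname)
            entry["replicates"].append(fname)
        manifest["samples"][s.sample_id] = entry
    truth.table.to_csv(directory / "truth.csv", index=False)
    manifest["error_model"] = truth.error_model
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
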