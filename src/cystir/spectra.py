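"""Spectrum containers, file I/O and wavenumber-grid conventions.

A :class:`Spectrum` is the package's universal currency: a strictly monotonic
wavenumber grid (stored descending, 4000 -> 750 cm^-1, the FTIR display
convention) and one absorbance value per grid point, plus free-form metadata.

The default working grid spans 4000-750 cm^-1 at 2 cm^-1 spacing, so the
cystine analysis wavenumbers (1296 and 1280 cm^-1) are exact grid points.
Band-position lookups accept a +/-1 cm^-1 tolerance, matching the quoted
frequency accuracy of a 4 cm^-1-resolution instrument; ties between equally
close grid points are broken toward the higher wavenumber.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import (
    GridRangeError,
    SpectrumFormatError,
    SpectrumValidationError,
)

#: Default grid: 4000 -> 750 cm^-1, 2 cm^-1 spacing, descending.
DEFAULT_GRID_START = 4000.0
DEFAULT_GRID_STOP = 750.0
DEFAULT_GRID_STEP = 2.0

#: Lookup tolerance for band positions, cm^-1.
BAND_LOOKUP_TOL = 1.0

#: Component names required by the urine pipeline.
REQUIRED_COMPONENTS = ("urea", "creatinine", "liquid_water", "water_vapour", "cystine")


def nearest_index(grid: np.ndarray, wn: float,
                  tol: float = BAND_LOOKUP_TOL) -> int:
    """Nearest index to `wn` on a descending grid, within `tol` cm^-1.

    Ties between equally close grid points break toward the higher
    wavenumber (first occurrence on a descending grid).
    """
    grid = np.asarray(grid, float)
    dist = np.abs(grid - wn)
    i = int(np.argmin(dist))
    if dist[i] > tol:
        raise GridRangeError(
            f"wavenumber {wn} cm^-1 not on grid within +/-{tol} cm^-1 "
            f"(coverage {grid.min()}-{grid.max()} cm^-1, "
            f"nearest point {grid[i]})")
    return i


def default_grid(start: float = DEFAULT_GRID_START,
                 stop: float = DEFAULT_GRID_STOP,
                 step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Return the descending working grid from `start` down to `stop`."""
    if start <= stop or step <= 0:
        raise SpectrumValidationError(
            f"invalid grid spec start={start}, stop={stop}, step={step}")
    n = int(round((start - stop) / step)) + 1
    return start - step * np.arange(n, dtype=float)


@dataclass
class Spectrum:
    """An absorbance spectrum on a strictly monotonic wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Grid in cm^-1, strictly monotonic, length >= 2.  Ascending input is
        accepted and silently reversed to the internal descending convention
        (a note is added to ``meta``).
    absorbance
        Absorbance (dimensionless), same length, all finite.
    meta
        Free-form key/value metadata (resolution, scans, sample id, ...).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise SpectrumValidationError("wavenumbers and absorbance must be 1-D")
        if wn.size < 2:
            raise SpectrumValidationError(
                f"spectrum needs at least 2 points, got {wn.size}")
        if wn.size != ab.size:
            raise SpectrumValidationError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbances")
        if not np.all(np.isfinite(wn)):
            raise SpectrumValidationError("wavenumbers contain NaN/Inf")
        if not np.all(np.isfinite(ab)):
            raise SpectrumValidationError("absorbance contains NaN/Inf")
        d = np.diff(wn)
        if np.all(d > 0):            # ascending input: flip to descending
            wn = wn[::-1].copy()
            ab = ab[::-1].copy()
            self.meta = dict(self.meta)
            self.meta.setdefault("orientation", "reversed from ascending input")
        elif not np.all(d < 0):
            raise SpectrumValidationError(
                "wavenumber grid must be strictly monotonic "
                "(duplicate or unordered values found)")
        self.wavenumbers = np.ascontiguousarray(wn)
        self.absorbance = np.ascontiguousarray(ab)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def coverage(self) -> tuple[float, float]:
        """(lowest, highest) wavenumber covered, cm^-1."""
        return float(self.wavenumbers[-1]), float(self.wavenumbers[0])

    def same_grid(self, other: "Spectrum") -> bool:
        return (len(self) == len(other)
                and np.array_equal(self.wavenumbers, other.wavenumbers))

    # -- lookups -----------------------------------------------------------
    def index_of(self, wn: float, tol: float = BAND_LOOKUP_TOL) -> int:
        """Nearest grid index to `wn`, within `tol` cm^-1.

        Ties between two equally close grid points go to the higher
        wavenumber (the first occurrence on the descending grid).
        """
        return nearest_index(self.wavenumbers, wn, tol)

    def value_at(self, wn: float, tol: float = BAND_LOOKUP_TOL) -> float:
        return float(self.absorbance[self.index_of(wn, tol)])

    def window_indices(self, wn_high: float, wn_low: float) -> np.ndarray:
        """Indices of the inclusive window [wn_high, wn_low] cm^-1.

        Endpoints are snapped to the nearest grid point (+/-1 cm^-1).
        """
        if wn_high < wn_low:
            wn_high, wn_low = wn_low, wn_high
        lo, hi = self.coverage
        if wn_high > hi + BAND_LOOKUP_TOL or wn_low < lo - BAND_LOOKUP_TOL:
            raise GridRangeError(
                f"window {wn_high}-{wn_low} cm^-1 exceeds coverage {hi}-{lo} cm^-1")
        i_hi = self.index_of(wn_high)
        i_lo = self.index_of(wn_low)
        return np.arange(i_hi, i_lo + 1)

    def with_absorbance(self, absorbance: np.ndarray, **meta) -> "Spectrum":
        """New Spectrum on the same grid with replaced absorbance."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(absorbance, float),
                        {**self.meta, **meta})


@dataclass
class ReferenceSet:
    """Named component spectra sharing one wavenumber grid."""

    components: dict[str, Spectrum]

    def __post_init__(self) -> None:
        if not self.components:
            raise SpectrumValidationError("ReferenceSet needs at least one component")
        grids = list(self.components.values())
        first = grids[0]
        for name, s in self.components.items():
            if not s.same_grid(first):
                raise SpectrumValidationError(
                    f"component {name!r} is not on the shared grid")

    @property
    def grid(self) -> np.ndarray:
        return next(iter(self.components.values())).wavenumbers

    def __getitem__(self, name: str) -> Spectrum:
        try:
            return self.components[name]
        except KeyError:
            raise KeyError(
                f"unknown component {name!r}; available: "
                f"{sorted(self.components)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.components

    def require(self, names: Iterable[str] = REQUIRED_COMPONENTS) -> None:
        missing = [n for n in names if n not in self.components]
        if missing:
            raise KeyError(f"reference set is missing components: {missing}")

    # -- serialization: directory of CSVs + manifest ----------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "cystir-reference-set/1",
            "grid": {
                "start_cm-1": float(self.grid[0]),
                "stop_cm-1": float(self.grid[-1]),
                "n_points": int(self.grid.size),
            },
            "components": {},
        }
        for name in sorted(self.components):
            fname = f"{name}.csv"
            write_spectrum(self.components[name], directory / fname, format="csv")
            manifest["components"][name] = fname
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceSet":
        directory = Path(directory)
        manifest_path = directory / "manifest.json"
        if not manifest_path.exists():
            raise SpectrumFormatError(f"no manifest.json in {directory}")
        manifest = json.loads(manifest_path.read_text())
        comps = {
            name: read_spectrum(directory / fname, format="csv")
            for name, fname in manifest["components"].items()
        }
        return cls(comps)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_JCAMP_SUFFIXES = {".jdx", ".dx", ".jcamp", ".jcm"}


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() in _JCAMP_SUFFIXES:
        return "jcamp"
    if path.suffix.lower() in {".csv", ".txt"}:
        return "csv"
    with open(path, "r", errors="replace") as fh:
        head = fh.read(512).lstrip()
    return "jcamp" if head.startswith("##") else "csv"


def read_spectrum(path: str | Path, format: str = "auto") -> Spectrum:
    """Read a spectrum from a JCAMP-DX or two-column CSV file.

    Ascending files are reversed to the internal descending convention and a
    metadata note is recorded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format == "jcamp":
        from . import jcampdx
        wn, ab, meta = jcampdx.read(path)
        return Spectrum(wn, ab, meta)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown spectrum format {format!r}")


def _read_csv(path: Path) -> Spectrum:
    wn: list[float] = []
    ab: list[float] = []
    meta: dict[str, str] = {}
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = [p for p in line.replace(";", ",").split(",") if p.strip()]
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if not wn and _looks_like_header(parts):
                    continue            # one optional header line
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric row {line!r}") from None
            wn.append(x)
            ab.append(y)
    if len(wn) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data rows")
    try:
        return Spectrum(np.array(wn), np.array(ab), meta)
    except SpectrumValidationError as exc:
        raise SpectrumValidationError(f"{path}: {exc}") from exc


def _looks_like_header(parts: list[str]) -> bool:
    for p in parts[:2]:
        try:
            float(p)
            return False
        except ValueError:
            pass
    return True


def write_spectrum(spectrum: Spectrum, path: str | Path, format: str = "csv") -> None:
    """Write a spectrum to CSV (with `#` metadata comments) or JCAMP-DX.

    Values are written with enough digits that a read-back reproduces the
    spectrum to better than 1e-9 relative error.
    """
    if len(spectrum) == 0:          # defensive; Spectrum forbids this anyway
        raise SpectrumValidationError("refusing to write an empty spectrum")
    path = Path(path)
    if format == "csv":
        lines = []
        for key in sorted(spectrum.meta):
            lines.append(f"# {key}: {spectrum.meta[key]}")
        lines.append("wavenumber_cm-1,absorbance")
        for x, y in zip(spectrum.wavenumbers, spectrum.absorbance):
            lines.append(f"{x:.12g},{y:.12g}")
        try:
            path.write_text("\n".join(lines) + "\n")
        except OSError as exc:
            raise OSError(f"cannot write spectrum to {path}: {exc}") from exc
        return
    if format == "jcamp":
        from . import jcampdx
        jcampdx.write(spectrum.wavenumbers, spectrum.absorbance, spectrum.meta, path)
        return
    raise ValueError(f"unknown spectrum format {format!r}")


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate `spectrum` onto `grid` (no extrapolation).

    Exact on piecewise-linear signals and the identity on the spectrum's own
    grid.  Raises :class:`GridRangeError` if `grid` exceeds coverage.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.coverage
    gmin, gmax = float(np.min(grid)), float(np.max(grid))
    eps = 1e-9 * max(abs(lo), abs(hi), 1.0)
    if gmin < lo - eps or gmax > hi + eps:
        raise GridRangeError(
            f"target grid [{gmin}, {gmax}] cm^-1 exceeds spectrum coverage "
            f"[{lo}, {hi}] cm^-1")
    # np.interp wants ascending support
    asc_wn = spectrum.wavenumbers[::-1]
    asc_ab = spectrum.absorbance[::-1]
    new_ab = np.interp(np.clip(grid, lo, hi), asc_wn, asc_ab)
    return Spectrum(grid.copy(), new_ab, dict(spectrum.meta))
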