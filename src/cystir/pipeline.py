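"""End-to-end analysis pipeline and run configuration.

``run_pipeline`` assembles the whole protocol: simulate (or load) a cohort,
build the cystine calibration from a dried-film standard series, remove
atmospheric contributions, quantify urea/creatinine by deconvolution and
insoluble cystine by the second-derivative calibration, apply the reporting
conventions, and compare against the clinical comparators.  Every run is a
pure function of its :class:`RunConfig` (including the seed), and all outputs
embed the config digest that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconvolve, preprocess, quantify, synth, validate
from .spectra import ReferenceSet, default_grid, read_spectrum

log = logging.getLogger("cystir.pipeline")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    n_patients: int = 22
    n_controls: int = 5
    grid_start: float = 4000.0
    grid_stop: float = 750.0
    grid_step: float = 2.0
    sg_window_points: int = preprocess.DEFAULT_SG_WINDOW
    sg_polyorder: int = preprocess.DEFAULT_SG_POLYORDER
    vapour_window: tuple[float, float] = preprocess.VAPOUR_FIT_WINDOW
    water_window: tuple[float, float] = preprocess.WATER_FIT_WINDOW
    deconv_window: tuple[float, float] = deconvolve.DEFAULT_WINDOW
    baseline_order: int = deconvolve.DEFAULT_BASELINE_ORDER
    calibration_mM: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    lod_sigma: float = quantify.LOD_SIGMA
    offset_mM: float = quantify.SOLUBILITY_OFFSET_MM
    original_volume_mL: float = 1.0
    resuspension_volume_mL: float = 1.0
    input_dir: str | None = None          # None -> simulate the cohort
    make_figures: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for k in ("vapour_window", "water_window", "deconv_window",
                  "calibration_mM"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def digest(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory result of one pipeline run."""

    config: RunConfig
    calibration: quantify.CalibrationModel
    results: list[quantify.QuantResult]
    samples_table: pd.DataFrame
    truth: synth.CohortTruth | None
    recovery_table: pd.DataFrame | None
    creatinine_comparison: validate.MethodComparison | None
    cystine_comparison: validate.MethodComparison | None


def load_cohort(directory: str | Path
                ) -> tuple[list[synth.CohortSample], synth.CohortTruth | None]:
    """Load a cohort directory written by :func:`cystir.synth.save_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    samples = []
    for sid, entry in sorted(manifest["samples"].items()):
        urine = read_spectrum(directory / entry["urine"])
        reps = [read_spectrum(directory / f) for f in entry["replicates"]]
        samples.append(synth.CohortSample(sid, urine, reps))
    truth = None
    truth_path = directory / "truth.csv"
    if truth_path.exists():
        truth = synth.CohortTruth(table=pd.read_csv(truth_path),
                                  error_model=manifest.get("error_model", {}))
    return samples, truth


def build_calibration(config: RunConfig, references: ReferenceSet,
                      grid: np.ndarray) -> quantify.CalibrationModel:
    """Simulate the 0-3 mM standard series and fit the through-origin line."""
    series = synth.generate_calibration_series(
        config.calibration_mM, seed=synth.derived_seed(config.seed, "calibration"),
        grid=grid)
    corrected = []
    for conc, s in series:
        c, _ = preprocess.subtract_atmosphere(
            s, references, vapour_window=config.vapour_window,
            include_water=False)
        corrected.append((conc, c))
    model, _ = quantify.calibrate_spectra(
        corrected, config.sg_window_points, config.sg_polyorder)
    model.meta.update(config_digest=config.digest,
                      series_mM=list(config.calibration_mM),
                      lod_sigma=config.lod_sigma)
    return model


def analyse_sample(sample: synth.CohortSample, config: RunConfig,
                   references: ReferenceSet,
                   calibration: quantify.CalibrationModel,
                   ) -> quantify.QuantResult:
    """Quantify one subject: urea/creatinine from urine, cystine from films."""
    sid = sample.sample_id
    log.info("stage=deconvolve sample=%s digest=%s", sid, config.digest)
    urine, _factors = preprocess.subtract_atmosphere(
        sample.urine_spectrum, references,
        vapour_window=config.vapour_window, water_window=config.water_window)
    fit = deconvolve.quantify_urine(
        urine, references, {"urea": 1.0, "creatinine": 1.0},
        window=config.deconv_window, baseline_order=config.baseline_order)
    log.info("stage=quantify sample=%s digest=%s", sid, config.digest)
    replicate_conc = []
    extrapolated = False
    for film in sample.insoluble_replicates:
        corrected_film, _ = preprocess.subtract_atmosphere(
            film, references, vapour_window=config.vapour_window,
            include_water=False)
        d2 = preprocess.second_derivative(
            corrected_film, config.sg_window_points, config.sg_polyorder)
        pred = quantify.predict_concentration(
            calibration, preprocess.cystine_response(d2))
        conc = quantify.apply_dilution(pred.concentration_mM,
                                       config.original_volume_mL,
                                       config.resuspension_volume_mL)
        replicate_conc.append(conc)
        extrapolated |= pred.extrapolated
    return quantify.report_sample(
        sid, replicate_conc,
        creatinine_mM=fit.concentrations["creatinine"],
        urea_mM=fit.concentrations["urea"],
        detection_threshold_mM=calibration.lod_mM,
        extrapolated=extrapolated)


def _samples_table(results: list[quantify.QuantResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "sample_id": r.sample_id,
            "insoluble_mM": r.insoluble_cystine_mM,
            "sem_mM": r.sem_mM,
            "detected": r.detected,
            "total_mM": r.total_cystine_mM,
            "censored": r.censored,
            "censored_halfwidth_mM": r.censored_halfwidth_mM,
            "creatinine_mM": r.creatinine_mM,
            "urea_mM": r.urea_mM,
            "ratio_uM_per_mM": (np.nan if r.ratio_uM_per_mM is None
                                else r.ratio_uM_per_mM),
            "extrapolated": r.extrapolated,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full protocol; optionally write the report to `outdir`.

    With ``config.input_dir`` unset the cohort is simulated from
    ``config.seed``; otherwise it is loaded from a cohort directory (truth
    and comparator values come from its ``truth.csv`` when present).
    """
    grid = default_grid(config.grid_start, config.grid_stop, config.grid_step)
    references = synth.reference_set_from_library(grid=grid)

    if config.input_dir is None:
        samples, truth = synth.generate_cohort(
            config.n_patients, config.n_controls, seed=config.seed, grid=grid)
    else:
        samples, truth = load_cohort(config.input_dir)

    calibration = build_calibration(config, references, grid)
    results = [analyse_sample(s, config, references, calibration)
               for s in samples]
    table = _samples_table(results)

    recovery = None
    creat_cmp = None
    cyst_cmp = None
    if truth is not None:
        tt = truth.table.set_index("sample_id")
        true_cols = tt[["group", "insoluble_cystine_mM", "creatinine_mM",
                        "urea_mM", "jaffe_creatinine_mM",
                        "iec_total_cystine_mM"]].rename(columns={
                            "insoluble_cystine_mM": "insoluble_mM_true",
                            "creatinine_mM": "creatinine_mM_true",
                            "urea_mM": "urea_mM_true"})
        recovery = table.set_index("sample_id").join(true_cols).reset_index()
        creat_pairs = [
            (float(tt.loc[r.sample_id, "jaffe_creatinine_mM"]),
             float(r.creatinine_mM), r.sample_id) for r in results]
        creat_cmp = validate.bland_altman(creat_pairs)
        creat_cmp.orientation = "jaffe - ftir"
        iec = {sid: float(v) for sid, v in
               tt["iec_total_cystine_mM"].items()}
        cyst_cmp = validate.comparison_with_offset(
            results, iec, offset=config.offset_mM)

    result = PipelineResult(config, calibration, results, table, truth,
                            recovery, creat_cmp, cyst_cmp)
    if outdir is not None:
        _write_report(result, Path(outdir))
    return result


def _write_report(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = res.config.to_dict()
    cfg["digest"] = res.config.digest
    (outdir / "config.json").write_text(
        json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    res.samples_table.to_csv(outdir / "samples.csv", index=False,
                             float_format="%.10g")
    res.calibration.to_json(outdir / "calibration.json")
    if res.recovery_table is not None:
        res.recovery_table.to_csv(outdir / "truth_recovery.csv", index=False,
                                  float_format="%.10g")
    if res.creatinine_comparison is not None:
        res.creatinine_comparison.to_json(outdir / "comparison_creatinine.json")
    if res.cystine_comparison is not None:
        res.cystine_comparison.to_json(outdir / "comparison_cystine.json")
    if res.config.make_figures:
        if res.creatinine_comparison is not None:
            validate.plot_comparison(res.creatinine_comparison,
                                     outdir / "creatinine_comparison.svg",
                                     title="Creatinine: Jaffe vs FTIR")
        if res.cystine_comparison is not None:
            validate.plot_comparison(res.cystine_comparison,
                                     outdir / "cystine_comparison.svg",
                                     title="Total cystine: IEC vs FTIR")
        _plot_cohort(res, outdir)


def _plot_cohort(res: PipelineResult, outdir: Path) -> None:
    """Per-sample bar charts of insoluble cystine and cystine:creatinine."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    t = res.samples_table
    for col, fname, ylabel in (
            ("insoluble_mM", "insoluble_cystine.svg", "insoluble cystine / mM"),
            ("ratio_uM_per_mM", "cystine_creatinine_ratio.svg",
             "cystine:creatinine / uM:mM")):
        fig, ax = plt.subplots(figsize=(8, 3.2))
        yerr = t["sem_mM"] if col == "insoluble_mM" else None
        ax.bar(t["sample_id"], t[col].fillna(0.0), yerr=yerr, capsize=2)
        ax.set_ylabel(ylabel)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=120)
        plt.close(fig)
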