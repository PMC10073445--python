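"""End-to-end workflow: standardize -> calibrate -> simulate -> quantify -> report.

``run_pipeline`` chains the phantom standardization, the counts-to-
concentration calibration, a synthetic patient cohort, a demonstration organ
quantification and the cohort statistics report into one provenance-stamped
output bundle.  Any stage failure aborts with the stage name; a fixed seed
makes the whole bundle bit-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationPoint, fit_calibration, reference_calibration
from .cohort import apply_event_recoding, get_preset, simulate_cohort
from .io import RunConfig, provenance
from .phantom import GridSpec, default_grid, generate_phantom_series, sphere_for_volume, \
    PhantomSpec, rasterize_phantom, apply_system_blur, add_poisson_noise
from .quantification import DoseRecord, organ_quant
from .segmentation import iso_contour_segment, roi_box_for, standardize_thresholds
from .stats import cox_regression, km_logrank, severity_strata_report

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger("qspect")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _provenance_line(config: RunConfig) -> str:
    p = provenance(config)
    return f"# provenance: config_hash={p['config_hash']} seed={p['seed']} version={p['version']}"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_line(config) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _write_json(payload: dict, path: Path, config: RunConfig) -> None:
    payload = {"provenance": provenance(config), **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig | None = None, outdir: str | Path = "qspect_out") -> dict:
    """Execute the full workflow and write the result bundle to ``outdir``.

    Artifacts: ``standardization.csv`` (per-range best thresholds and
    estimated/true volumes), ``calibration.json`` (fitted regression line),
    ``cohort.csv`` (synthetic patient table), ``quant.json`` (demonstration
    organ quantification on a simulated liver-sized phantom) and
    ``report.json`` (stratified statistics + survival analysis).  Returns
    the bundle as a dict of in-memory results.
    """
    if config is None:
        config = RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = default_grid()
    rng_seed = int(config.seed)
    bundle: dict = {}

    stage = "standardize"
    try:
        logger.info("stage %s: phantom series + threshold sweep", stage)
        volumes = [v for rng_vols in config.range_volumes_mL for v in rng_vols]
        mid_conc = config.concentrations_uCi_per_mL[len(config.concentrations_uCi_per_mL) // 2]
        series = generate_phantom_series(
            volumes, [mid_conc], grid=grid, fwhm_mm=config.fwhm_mm,
            noise=config.noise, seed=rng_seed)
        standardizations = standardize_thresholds(
            series, ranges=[tuple(r) for r in config.volume_ranges],
            thresholds=config.thresholds())
        rows = []
        for st in standardizations:
            for vt, ve in zip(st.true_volumes_mL, st.estimated_volumes_mL):
                rows.append({
                    "range_low_mL": st.range_mL[0], "range_high_mL": st.range_mL[1],
                    "best_threshold_pct": st.best_threshold,
                    "volume_correlation_r": st.volume_correlation_r,
                    "true_volume_mL": vt, "estimated_volume_mL": ve,
                })
        _write_csv(pd.DataFrame(rows), outdir / "standardization.csv", config)
        bundle["standardization"] = standardizations
    except Exception as err:  # noqa: BLE001 - rewrap with stage name
        raise PipelineError(stage, err) from err

    stage = "calibrate"
    try:
        logger.info("stage %s: concentration series at %.1f%% threshold",
                    stage, config.calibration_threshold_pct)
        cal_volume = 1000.0
        points = []
        for i, conc in enumerate(config.concentrations_uCi_per_mL):
            spec = PhantomSpec(geometry=sphere_for_volume(cal_volume, grid.center_mm),
                               concentration=conc)
            vol = rasterize_phantom(spec, grid)
            vol = apply_system_blur(vol, config.fwhm_mm)
            if config.noise:
                vol = add_poisson_noise(vol, rng_seed + 1000 + i)
            seg = iso_contour_segment(vol, config.calibration_threshold_pct,
                                      roi_box_for(spec, grid))
            mean_counts_per_cc = seg.mean_counts_per_voxel / grid.voxel_volume_mL
            points.append(CalibrationPoint(mean_counts_per_cc, conc))
        calibration = fit_calibration(points, threshold_pct=config.calibration_threshold_pct)
        calibration.to_json(outdir / "calibration.json", provenance=provenance(config))
        bundle["calibration"] = calibration
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    stage = "cohort"
    try:
        logger.info("stage %s: preset %s n=%d", stage, config.cohort_preset, config.cohort_n)
        cohort_cfg = get_preset(config.cohort_preset, n=config.cohort_n, seed=rng_seed)
        cohort = simulate_cohort(cohort_cfg)
        _write_csv(cohort, outdir / "cohort.csv", config)
        bundle["cohort"] = cohort
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    stage = "quant"
    try:
        logger.info("stage %s: demonstration liver quantification", stage)
        dose = DoseRecord(injected_activity_MBq=166.0)
        liver_spec = PhantomSpec(geometry=sphere_for_volume(1200.0, grid.center_mm),
                                 concentration=1.0)
        vol = rasterize_phantom(liver_spec, grid)
        vol = apply_system_blur(vol, config.fwhm_mm)
        if config.noise:
            vol = add_poisson_noise(vol, rng_seed + 2000)
        seg = iso_contour_segment(vol, config.calibration_threshold_pct,
                                  roi_box_for(liver_spec, grid))
        quant = organ_quant(vol, seg, reference_calibration(), dose, organ="liver",
                            decay_correction=config.decay_correction)
        _write_json({
            "organ": quant.organ,
            "volume_mL": quant.volume_mL,
            "organ_activity_uCi": quant.organ_activity_uCi,
            "pct_uptake": quant.pct_uptake,
            "pct_id_per_mL": quant.pct_id_per_mL,
            "decay_corrected": quant.decay_corrected,
        }, outdir / "quant.json", config)
        bundle["quant"] = quant
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    stage = "stats"
    try:
        logger.info("stage %s: cohort report + survival", stage)
        cohort = bundle["cohort"]
        report: dict = {}
        if set(cohort["ctp_class"].unique()) >= {"A", "B", "C"}:
            report["strata"] = severity_strata_report(cohort)
        events = apply_event_recoding(cohort)
        surv = km_logrank(cohort["time_months"], events, cohort["arm"])
        cox = cox_regression(
            pd.DataFrame({"gcsf": (cohort["arm"] == "GCSF").astype(float),
                          "meld": cohort["meld"].astype(float)}),
            cohort["time_months"], events)
        report["survival"] = {
            "logrank_stat": surv.logrank_stat,
            "logrank_p": surv.logrank_p,
            "km_12mo": {str(lab): surv.km_survival_at(lab, 12.0) for lab in surv.km_curves},
            "cox": [{"name": c.name, "hazard_ratio": c.hazard_ratio,
                     "ci95": list(c.ci95), "p": c.p} for c in cox.cox],
        }
        _write_json(report, outdir / "report.json", config)
        bundle["report"] = report
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    config.to_json(outdir / "config.json")
    return bundle
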