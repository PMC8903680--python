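"""End-to-end pipeline driver.

simulate -> preprocess (QC, scale, baseline, calibrate, align) ->
quantify (deconvolve, discard, PLS rescue, assign) -> postprocess
(filter, transform, kinship, Z-score) -> model (lifetime and active
endpoints) -> report.  Each stage is an importable function over plain
objects; ``run_pipeline`` chains them in memory and produces a
:class:`RunReport` with per-stage sample counts and exclusions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .cow import apply_warp, cow_align
from .deconvolution import deconvolve_peaks, initial_peaks_from_catalog
from .modeling import (
    InferenceReport,
    compute_weighted_score,
    covariate_influence,
    demographics_table,
    endpoint_rows,
    fit_score_logistic,
    select_signals_enet,
)
from .postprocess import postprocess_signals
from .preprocess import (
    calibrate_ppm,
    median_reference,
    qc_spectra,
    regrid,
    scale_receiver_sensitivity,
    subtract_constant_baseline,
)
from .quantify import build_signal_table, load_reference_shifts
from .simulate import (
    default_ppm_grid,
    default_templates,
    generate_cohort,
    generate_concentrations,
    render_spectra,
)
from .types import SignalTable, Spectrum1D, JresProjection, spectra_to_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "PipelineResult",
    "simulate_stage",
    "preprocess_stage",
    "quantify_stage",
    "postprocess_stage",
    "model_stage",
]


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    truth: object
    signal_table: SignalTable
    zscores: pd.DataFrame
    processing_log: pd.DataFrame
    reports: dict[str, InferenceReport]
    demographics: dict[str, pd.DataFrame]
    covariate_influence: dict[str, pd.DataFrame]
    run_report: dict
    qc_flags: pd.DataFrame | None = None
    warp_paths: dict = field(default_factory=dict)


def _templates(config: RunConfig):
    templates = default_templates()
    if config.max_metabolites is not None:
        templates = templates[: config.max_metabolites]
    return templates


def simulate_stage(config: RunConfig):
    """Cohort, concentrations and rendered paired spectra."""
    templates = _templates(config)
    cohort_cfg = config.cohort
    cohort_cfg.seed = config.seed
    cohort = generate_cohort(cohort_cfg)
    truth = generate_concentrations(cohort, templates, cohort_cfg)
    ppm = default_ppm_grid(config.grid_high, config.grid_low, config.grid_step)
    spectra, projections = render_spectra(
        truth, templates, config.spectra, ppm=ppm, seed=config.seed
    )
    return cohort, truth, templates, spectra, projections


def preprocess_stage(
    config: RunConfig,
    spectra: list[Spectrum1D],
    projections: list[JresProjection],
):
    """QC, scaling, baseline, calibration, COW; returns aligned data.

    Returns (qc_flags, warped projections, non-warped CPMG matrix,
    warp paths, exclusions dict).
    """
    qc_flags = qc_spectra(spectra, config.qc) if config.qc_enabled else None
    if qc_flags is not None:
        passed = set(qc_flags.index[qc_flags["passed"]])
    else:
        passed = {s.sample_id for s in spectra}
    by_id = {p.sample_id: p for p in projections}
    grid = spectra[0].ppm if spectra else None

    calibrated: list[Spectrum1D] = []
    calibrated_proj: list[JresProjection] = []
    shifts = {}
    excluded = {}
    for s in spectra:
        if s.sample_id not in passed:
            excluded[s.sample_id] = "qc"
            continue
        s = scale_receiver_sensitivity(s, config.spectra.reference_pulse_length_us)
        s, _ = subtract_constant_baseline(s, config.baseline_windows)
        try:
            s, shift = calibrate_ppm(
                s, config.calibration_target_ppm, config.calibration_halfwidth_ppm
            )
        except ValueError as exc:
            excluded[s.sample_id] = f"calibration: {exc}"
            continue
        shifts[s.sample_id] = shift
        calibrated.append(regrid(s, grid))

        proj = by_id[s.sample_id]
        # same receiver scaling, baseline rule and ppm shift as the CPMG
        pj = Spectrum1D(
            sample_id=proj.sample_id,
            ppm=proj.ppm,
            intensity=proj.intensity,
            pulse_length_us=s.pulse_length_us,
        )
        pj = scale_receiver_sensitivity(pj, config.spectra.reference_pulse_length_us)
        pj, _ = subtract_constant_baseline(pj, config.baseline_windows)
        pj = pj.with_ppm(pj.ppm + shift)
        calibrated_proj.append(
            JresProjection(
                sample_id=proj.sample_id,
                ppm=grid,
                intensity=regrid(pj, grid).intensity,
            )
        )

    if not calibrated:
        raise RuntimeError("preprocess: no spectra survived QC/calibration")
    reference = median_reference(calibrated)
    warped_proj = []
    paths = {}
    for s, pj in zip(calibrated, calibrated_proj):
        aligned, path = cow_align(
            s,
            reference,
            config.cow_segment_length,
            config.cow_slack,
            max_drift=config.cow_max_drift,
        )
        paths[s.sample_id] = path
        warped_proj.append(apply_warp(path, pj))
    nonwarped = spectra_to_matrix(calibrated)
    return qc_flags, warped_proj, nonwarped, paths, excluded


def quantify_stage(
    config: RunConfig,
    warped_projections: list[JresProjection],
    nonwarped: pd.DataFrame,
    catalog: pd.DataFrame,
) -> SignalTable:
    """Per-sample deconvolution and signal-table assembly."""
    initial = initial_peaks_from_catalog(catalog, config.spectra.jres_width_factor)
    areas = {}
    status = {}
    for i, proj in enumerate(warped_projections):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505, i]))
        res = deconvolve_peaks(
            proj, initial, config.fit_window_halfwidth_ppm, rng=rng
        )
        areas[proj.sample_id] = res.areas
        status[proj.sample_id] = res.status
    areas_df = pd.DataFrame.from_dict(areas, orient="index")
    status_df = pd.DataFrame.from_dict(status, orient="index")
    signals = catalog[["shift_ppm"]].copy()
    n_comp = min(config.pls_components, max(1, len(areas_df) - 2))
    return build_signal_table(
        areas_df,
        status_df,
        signals,
        nonwarped,
        n_components=n_comp,
        reference=load_reference_shifts(),
        correlation_threshold=config.assignment_correlation_threshold,
    )


def postprocess_stage(
    config: RunConfig, table: SignalTable, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    families = cohort.set_index("subject_id")["family_id"]
    return postprocess_signals(
        table,
        families,
        kinship_method=config.kinship_method,
        shapiro_alpha=config.shapiro_alpha,
    )


def model_stage(
    config: RunConfig,
    zscores: pd.DataFrame,
    cohort: pd.DataFrame,
    endpoints: tuple[str, ...] = ("lifetime", "active"),
):
    """Elastic-net selection + weighted-score inference per endpoint."""
    cix = cohort.set_index("subject_id")
    reports: dict[str, InferenceReport] = {}
    demo: dict[str, pd.DataFrame] = {}
    cov_inf: dict[str, pd.DataFrame] = {}
    for endpoint in endpoints:
        mask, y = endpoint_rows(cix, endpoint)
        rows = cix.index[mask].intersection(zscores.index)
        Z = zscores.loc[rows]
        yy = y.loc[rows]
        if int(yy.sum()) < 5 or int((1 - yy).sum()) < 5:
            logger.warning("%s: too few cases or controls; endpoint skipped", endpoint)
            continue
        folds = min(config.enet_folds, int(yy.sum()), int((1 - yy).sum()))
        enet = select_signals_enet(
            Z,
            yy,
            alpha=config.enet_alpha,
            folds=folds,
            lambda_rule=config.lambda_rule,
            seed=config.seed,
            n_lambdas=config.n_lambdas,
            cv_mode=config.cv_mode,
        )
        if not enet.selected_signal_ids:
            logger.warning("%s: empty elastic-net selection", endpoint)
            continue
        score = compute_weighted_score(Z[enet.selected_signal_ids], yy)
        covariates = cix.loc[score.scores.index, ["age", "sex", "bmi", "smoking"]]
        try:
            report = fit_score_logistic(score.scores, yy, covariates, endpoint=endpoint)
        except ValueError as exc:
            logger.warning("%s: %s; endpoint skipped", endpoint, exc)
            continue
        report.selected_signals = enet.selected_signal_ids
        reports[endpoint] = report
        demo[endpoint] = demographics_table(cix, endpoint)
        cov_inf[endpoint], _ = covariate_influence(score.scores, covariates)
    return reports, demo, cov_inf


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage in memory; fully reproducible under one seed."""
    cohort, truth, templates, spectra, projections = simulate_stage(config)
    n0 = len(spectra)
    qc_flags, warped_proj, nonwarped, paths, excluded = preprocess_stage(
        config, spectra, projections
    )
    table = quantify_stage(config, warped_proj, nonwarped, truth.catalog)
    zscores, proc_log = postprocess_stage(config, table, cohort)
    reports, demo, cov_inf = model_stage(config, zscores, cohort)

    run_report = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {
            "simulated": n0,
            "qc_excluded": sum(1 for r in excluded.values() if r == "qc"),
            "calibration_excluded": sum(
                1 for r in excluded.values() if r.startswith("calibration")
            ),
            "quantified": len(table.sample_ids),
            "modeled": {e: r.n_cases_used + r.n_controls_used for e, r in reports.items()},
        },
        "exclusions": excluded,
        "endpoints": {e: r.to_dict() for e, r in reports.items()},
    }
    assert run_report["counts"]["simulated"] == (
        len(table.sample_ids) + len(excluded)
    ), "stage counts are inconsistent"
    return PipelineResult(
        cohort=cohort,
        truth=truth,
        signal_table=table,
        zscores=zscores,
        processing_log=proc_log,
        reports=reports,
        demographics=demo,
        covariate_influence=cov_inf,
        run_report=run_report,
        qc_flags=qc_flags,
        warp_paths=paths,
    )
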