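"""End-to-end orchestration: curves -> maps -> regions -> validated models.

``analyze_cohort`` drives the in-memory analysis used by the tests and the
CLI alike: clinical reference model (with bootstrap), standard dose-metric
screen, one interaction map per (density metric, dose metric) pair, region
extraction with the size filter, candidate Cox models, bootstrap stability
filtering, and a Table-3-style summary for the best retained region.
``run_all`` wraps it with file I/O and a reproducible run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import scan as scan_mod
from . import validate as val_mod
from .config import ScanSettings, config_to_dict
from .errors import DataError
from .survival import (
    CoxFit,
    clinical_design,
    endpoint_columns,
    fit_cox,
    standard_dose_metric_screen,
)
from .synthetic import Cohort

__all__ = ["AnalysisResult", "analyze_cohort", "run_all"]

INTERACTION_TERM = "density_x_dose"


@dataclass
class AnalysisResult:
    settings: ScanSettings
    clinical_fit: CoxFit
    clinical_bootstrap: val_mod.BootstrapReport | None
    screen: pd.DataFrame | None
    maps: dict
    regions: list
    reports: dict  # region index -> BootstrapReport
    models: dict  # region index -> (reduced CoxFit, full CoxFit)
    retained: list
    best_index: int | None
    summary: pd.DataFrame | None
    contrast: val_mod.ContrastData | None = None
    stratification: val_mod.StratificationData | None = None
    seeds: dict = field(default_factory=dict)


def _spawn_seeds(root_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root_seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def analyze_cohort(
    cohort: Cohort | None = None,
    settings: ScanSettings | None = None,
    *,
    curves: dict | None = None,
    clinical: pd.DataFrame | None = None,
    density_centers=None,
    dose_centers=None,
    dose_stats: pd.DataFrame | None = None,
    filled: dict | None = None,
    with_interpretation: bool = True,
) -> AnalysisResult:
    """Run the full analysis on a cohort (in memory).

    Either pass a :class:`Cohort` or the raw pieces (curves, clinical
    table, bin centers).  ``with_interpretation`` adds contrast curves and
    the KM stratification for the best retained region.
    """
    settings = settings or ScanSettings()
    settings.validate()
    if cohort is not None:
        curves = cohort.curves
        clinical = cohort.clinical
        density_centers = cohort.density_centers
        dose_centers = cohort.dose_centers
        if dose_stats is None:
            dose_stats = cohort.dose_stats
        if filled is None:
            filled = cohort.filled
    if curves is None or clinical is None:
        raise ValueError("need a cohort or curves + clinical table")
    fill_fraction = None
    if filled:
        fill_fraction = {m: np.asarray(v, dtype=float).mean(axis=0) for m, v in filled.items()}

    tcol, ecol = endpoint_columns(settings.endpoint)
    time = clinical[tcol].to_numpy(dtype=float)
    event = clinical[ecol].to_numpy()
    design = clinical_design(clinical)
    clinical_fit = fit_cox(design, time, event)

    n_pairs = len(settings.density_metrics) * len(settings.dose_metrics)
    seeds = _spawn_seeds(settings.seed, 3 + n_pairs * 64)
    seed_iter = iter(seeds)
    clinical_seed = next(seed_iter)

    screen = None
    if dose_stats is not None:
        cols = [c for c in dose_stats.columns if c != "patient_id"]
        screen = standard_dose_metric_screen(clinical, dose_stats[cols], settings.endpoint)

    maps = {}
    regions: list = []
    for dm in settings.density_metrics:
        for zm in settings.dose_metrics:
            imap = scan_mod.scan(
                curves,
                clinical,
                density_centers,
                dose_centers,
                endpoint=settings.endpoint,
                density_metric=dm,
                dose_metric=zm,
                density_range_mm=settings.density_range_mm,
                dose_range_mm=settings.dose_range_mm,
                alpha=settings.alpha,
                fill_fraction=fill_fraction,
            )
            maps[(dm, zm)] = imap
            regions.extend(
                scan_mod.extract_regions(imap, min_thickness_mm=settings.min_thickness_mm)
            )

    reports, models = {}, {}
    candidates = [i for i, r in enumerate(regions) if r.status != "below_size"]
    # the clinical bootstrap is only consumed by the stability filter and the
    # summary table; skip it when the size filter already rejected everything
    clinical_boot = None
    if candidates:
        try:
            clinical_boot = val_mod.bootstrap_validate(
                design, time, event, n_resamples=settings.n_bootstrap, seed=clinical_seed
            )
        except DataError:
            warnings.warn("clinical-model bootstrap failed; candidate regions left unvalidated")
    for i in candidates:
        region = regions[i]
        dens, dose = scan_mod.region_values(region, curves, density_centers, dose_centers)
        reduced, full = scan_mod.candidate_model(dens, dose, clinical, settings.endpoint)
        models[i] = (reduced, full)
        full_design = _candidate_design(dens, dose, clinical)
        if clinical_boot is None:
            region.status = "unstable"
            region.details["bootstrap"] = "clinical bootstrap failed"
            continue
        # same seed as the clinical bootstrap: paired resamples, so the
        # C-gain comparison in the stability filter is a paired difference
        # rather than a race between two independently noisy estimates
        try:
            reports[i] = val_mod.bootstrap_validate(
                full_design,
                time,
                event,
                n_resamples=settings.n_bootstrap,
                seed=clinical_seed,
                interaction_term=INTERACTION_TERM,
            )
        except DataError:
            region.status = "unstable"
            region.details["bootstrap"] = "no resample converged"
    validated = [i for i in candidates if i in reports]
    retained = val_mod.stability_filter(
        [regions[i] for i in validated], [reports[i] for i in validated], clinical_boot
    )

    best_index = None
    ranked = [i for i in candidates if regions[i].status == "retained"]
    if ranked:
        best_index = min(ranked, key=lambda i: regions[i].min_p)

    summary = None
    contrast_data = None
    strat = None
    if best_index is not None:
        region = regions[best_index]
        reduced, full = models[best_index]
        red_design = _candidate_design(
            region.patient_density_hu, region.patient_dose_gy, clinical, interaction=False
        )
        red_boot = val_mod.bootstrap_validate(
            red_design, time, event, n_resamples=settings.n_bootstrap, seed=clinical_seed
        )
        full_boot = reports[best_index]
        summary = pd.DataFrame(
            [
                _summary_row("clinical", clinical_fit, clinical_boot),
                _summary_row("clinical + dose + density", reduced, red_boot),
                _summary_row("clinical + dose + density + interaction", full, full_boot),
            ]
        )
        if with_interpretation:
            dose_gy = region.patient_dose_gy
            z_centered = dose_gy - dose_gy.mean()
            refs = np.quantile(z_centered, [0.1, 0.5, 0.9])
            dens_hu = region.patient_density_hu
            grid = np.linspace(dens_hu.min(), dens_hu.max(), 61)
            contrast_data = val_mod.contrast(
                full,
                "density_100hu",
                INTERACTION_TERM,
                refs,
                grid,
                reference_density_hu=float(np.median(dens_hu)),
            )
            strat = val_mod.km_stratify(time, event, dens_hu, dose_gy)

    return AnalysisResult(
        settings=settings,
        clinical_fit=clinical_fit,
        clinical_bootstrap=clinical_boot,
        screen=screen,
        maps=maps,
        regions=regions,
        reports=reports,
        models=models,
        retained=retained,
        best_index=best_index,
        summary=summary,
        contrast=contrast_data,
        stratification=strat,
        seeds={"root": settings.seed},
    )


def _candidate_design(density_hu, dose_gy, clinical, interaction: bool = True) -> pd.DataFrame:
    design = clinical_design(clinical).copy()
    x = np.asarray(density_hu, dtype=float) / scan_mod.DENSITY_SCALE_HU
    z = np.asarray(dose_gy, dtype=float)
    design["density_100hu"] = x - x.mean()
    design["dose_gy"] = z - z.mean()
    if interaction:
        design[INTERACTION_TERM] = design["density_100hu"] * design["dose_gy"]
    return design


def _summary_row(name: str, fit: CoxFit, boot: val_mod.BootstrapReport) -> dict:
    return {
        "model": name,
        "c_training": fit.cindex,
        "c_boot_median": boot.c_median,
        "c_boot_ci_low": boot.c_ci[0],
        "c_boot_ci_high": boot.c_ci[1],
        "c_optimism_adjusted": boot.c_adjusted,
        "aic": fit.aic,
        "loglik": fit.loglik,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cohort_dir, out_dir, settings: ScanSettings | None = None) -> dict:
    """File-based pipeline: read a cohort directory, write all artifacts.

    Stages: extract -> clinical model + dose-metric screen -> scans ->
    region selection -> internal validation.  Returns the manifest (also
    written as ``manifest.json``): config snapshot, per-stage wall-clock,
    and SHA-256 hashes of every written artifact.
    """
    settings = settings or ScanSettings()
    settings.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config_to_dict(settings),
        "stages": {},
        "outputs": {},
    }

    t0 = _time.perf_counter()
    curves, density_centers, dose_centers, dose_stats, clinical, filled = cio.extract_cohort_dir(
        cohort_dir, settings
    )
    cio.save_curves_csv(
        out_dir / "curves.csv", curves, density_centers, dose_centers, clinical, filled
    )
    dose_stats.to_csv(out_dir / "dose_stats.csv", index=False)
    manifest["stages"]["extract"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    result = analyze_cohort(
        settings=settings,
        curves=curves,
        clinical=clinical,
        density_centers=density_centers,
        dose_centers=dose_centers,
        dose_stats=dose_stats,
        filled=filled,
    )
    manifest["stages"]["analyze"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    cio.save_analysis(out_dir, result)
    manifest["stages"]["write"] = _time.perf_counter() - t0

    for p in sorted(out_dir.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
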