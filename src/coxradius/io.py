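"""File interfaces: NIfTI volumes, tidy curve CSVs, analysis artifacts.

A cohort directory holds one subdirectory per patient with ``density``,
``dose``, ``gtv`` and ``lung`` NIfTI volumes (spacing in the affine), plus
``clinical.csv`` and, for synthetic cohorts, ``config.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .config import ScanSettings, config_to_dict
from .errors import SchemaError
from .extract import extract_patient
from .synthetic import Cohort

__all__ = [
    "save_cohort",
    "iter_cohort_volumes",
    "extract_cohort_dir",
    "save_curves_csv",
    "load_curves_csv",
    "save_analysis",
]

VOLUME_NAMES = ("density", "dose", "gtv", "lung")


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a simulated cohort (volumes + clinical table + config)."""
    if not cohort.patients:
        raise ValueError("cohort was simulated without keep_volumes=True")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort.patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        aff = _affine(p.spacing)
        nib.save(nib.Nifti1Image(p.density.astype(np.float32), aff), pdir / "density.nii")
        nib.save(nib.Nifti1Image(p.dose.astype(np.float32), aff), pdir / "dose.nii")
        nib.save(nib.Nifti1Image(p.gtv.astype(np.uint8), aff), pdir / "gtv.nii")
        nib.save(nib.Nifti1Image(p.lung.astype(np.uint8), aff), pdir / "lung.nii")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.dose_stats.to_csv(out / "dose_stats.csv", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(config_to_dict(cohort.config), fh, indent=2)
    return out


def iter_cohort_volumes(cohort_dir):
    """Yield (patient_id, density, dose, gtv, lung, spacing) per patient."""
    cohort_dir = Path(cohort_dir)
    clin_path = cohort_dir / "clinical.csv"
    if not clin_path.exists():
        raise SchemaError(
            f"{cohort_dir} has no clinical.csv; run the 'simulate' step first"
        )
    clinical = pd.read_csv(clin_path)
    for pid in clinical["patient_id"]:
        pdir = cohort_dir / str(pid)
        vols = {}
        for name in VOLUME_NAMES:
            path = pdir / f"{name}.nii"
            if not path.exists():
                raise SchemaError(f"missing volume {path}")
            img = nib.load(path)
            vols[name] = np.asarray(img.dataobj)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        yield (
            str(pid),
            vols["density"].astype(np.float32),
            vols["dose"].astype(np.float32),
            vols["gtv"].astype(bool),
            vols["lung"].astype(bool),
            spacing,
        )


def extract_cohort_dir(cohort_dir, settings: ScanSettings | None = None):
    """Extract curves and dose statistics for every patient in a directory.

    Returns ``(curves, density_centers, dose_centers, dose_stats, clinical,
    filled)`` with ``curves[metric]`` an (n_patients, n_bins) array and
    ``filled[metric]`` the matching imputed-annulus flags.
    """
    settings = settings or ScanSettings()
    cohort_dir = Path(cohort_dir)
    if not (cohort_dir / "clinical.csv").exists():
        raise SchemaError(
            f"{cohort_dir} has no clinical.csv; run the 'simulate' step (or point "
            "--cohort at a directory with per-patient volumes and a clinical table)"
        )
    clinical = pd.read_csv(cohort_dir / "clinical.csv")
    cfg_path = cohort_dir / "config.json"
    n_fractions = 5
    if cfg_path.exists():
        with open(cfg_path) as fh:
            n_fractions = json.load(fh).get("dose_plan", {}).get("n_fractions", 5)

    curve_rows: dict[str, list[np.ndarray]] = {}
    filled_rows: dict[str, list[np.ndarray]] = {}
    stats_rows = []
    density_centers = dose_centers = None
    motion = dict(zip(clinical["patient_id"].astype(str), clinical["motion_cm"]))
    for pid, density, dose, gtv, lung, spacing in iter_cohort_volumes(cohort_dir):
        feats = extract_patient(
            density,
            dose,
            gtv,
            lung,
            spacing,
            n_fractions,
            float(motion[pid]),
            alpha_beta_gy=settings.alpha_beta_gy,
            sigma_mm=settings.smoothing_sigma_mm,
            dose_range_mm=settings.dose_extraction_range_mm,
            eqd2_threshold_gy=settings.eqd2_threshold_gy,
        )
        for name, c in feats.curves.items():
            curve_rows.setdefault(name, []).append(c.values)
            flags = np.zeros(len(c.values), dtype=bool)
            flags[c.filled_bins] = True
            filled_rows.setdefault(name, []).append(flags)
        density_centers = feats.curves["density_mean"].distance_mm
        dose_centers = feats.curves["dose_sd"].distance_mm
        stats_rows.append(
            {
                "patient_id": pid,
                **{f"GTV_{k}": getattr(feats.gtv_stats, k) for k in ("mean", "max", "min", "sd")},
                **{f"PTV_{k}": getattr(feats.ptv_stats, k) for k in ("mean", "max", "min", "sd")},
            }
        )
    curves = {k: np.vstack(v) for k, v in curve_rows.items()}
    filled = {k: np.vstack(v) for k, v in filled_rows.items()}
    return curves, density_centers, dose_centers, pd.DataFrame(stats_rows), clinical, filled


def save_curves_csv(path, curves, density_centers, dose_centers, clinical, filled=None) -> None:
    """Tidy per-patient curves: patient_id, metric, distance_mm, value, filled."""
    pids = clinical["patient_id"].astype(str).to_numpy()
    frames = []
    for metric, mat in curves.items():
        centers = density_centers if metric.startswith("density") else dose_centers
        n, m = mat.shape
        flags = (
            np.asarray(filled[metric]).astype(int).ravel()
            if filled and metric in filled
            else np.zeros(n * m, dtype=int)
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(pids, m),
                    "metric": metric,
                    "distance_mm": np.tile(np.asarray(centers), n),
                    "value": np.asarray(mat).ravel(),
                    "filled": flags,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_curves_csv(path):
    """Inverse of :func:`save_curves_csv`.

    Returns ``(curves, density_centers, dose_centers, patient_ids, filled)``.
    """
    tidy = pd.read_csv(path)
    if "filled" not in tidy.columns:
        tidy["filled"] = 0
    curves = {}
    filled = {}
    density_centers = dose_centers = None
    pids = tidy["patient_id"].astype(str).unique()
    order = {p: i for i, p in enumerate(pids)}
    for metric, grp in tidy.groupby("metric", sort=False):
        piv = grp.pivot_table(
            index="patient_id", columns="distance_mm", values="value", sort=True
        )
        piv = piv.loc[sorted(piv.index, key=order.get)]
        curves[metric] = piv.to_numpy()
        fpiv = grp.pivot_table(
            index="patient_id", columns="distance_mm", values="filled", sort=True
        )
        filled[metric] = fpiv.loc[piv.index].to_numpy().astype(bool)
        centers = piv.columns.to_numpy(dtype=float)
        if metric.startswith("density"):
            density_centers = centers
        else:
            dose_centers = centers
    return curves, density_centers, dose_centers, pids, filled


def save_map_csv(path, imap) -> None:
    df = pd.DataFrame(
        imap.p_values,
        index=pd.Index(imap.density_centers_mm, name="density_mm"),
        columns=pd.Index(imap.dose_centers_mm, name="dose_mm"),
    )
    df.to_csv(path)


def regions_table(regions) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(regions):
        rows.append(
            {
                "region": i,
                "density_metric": r.density_metric,
                "dose_metric": r.dose_metric,
                "density_lo_mm": r.density_interval_mm[0],
                "density_hi_mm": r.density_interval_mm[1],
                "dose_lo_mm": r.dose_interval_mm[0],
                "dose_hi_mm": r.dose_interval_mm[1],
                "thickness_density_mm": r.thickness_density_mm,
                "thickness_dose_mm": r.thickness_dose_mm,
                "min_p": r.min_p,
                "status": r.status,
                **{k: v for k, v in r.details.items()},
            }
        )
    return pd.DataFrame(rows)


def save_analysis(out_dir, result) -> None:
    """Write maps, region table, model summaries and validation JSON."""
    out_dir = Path(out_dir)
    for (dm, zm), imap in result.maps.items():
        save_map_csv(out_dir / f"map_{dm}_{zm}.csv", imap)
        meta = {
            "density_metric": dm,
            "dose_metric": zm,
            "endpoint": imap.endpoint,
            "alpha": imap.alpha,
            "density_range_mm": [float(imap.density_centers_mm[0] - 0.5),
                                 float(imap.density_centers_mm[-1] + 0.5)],
            "dose_range_mm": [float(imap.dose_centers_mm[0] - 0.5),
                              float(imap.dose_centers_mm[-1] + 0.5)],
        }
        with open(out_dir / f"map_{dm}_{zm}.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    regions_table(result.regions).to_csv(out_dir / "regions.csv", index=False)
    result.clinical_fit.summary().to_csv(out_dir / "clinical_model.csv", index=False)
    if result.screen is not None:
        result.screen.to_csv(out_dir / "dose_metric_screen.csv", index=False)
    if result.summary is not None:
        result.summary.to_csv(out_dir / "validation_summary.csv", index=False)
    if result.best_index is not None:
        reduced, full = result.models[result.best_index]
        full.summary().to_csv(out_dir / "final_model.csv", index=False)
        reduced.summary().to_csv(out_dir / "final_model_no_interaction.csv", index=False)
        lrt = likelihood_ratio_test_safe(full, reduced)
        report = result.reports[result.best_index]
        payload = {
            "interaction_lrt_p": lrt,
            "interaction_sig_frac": report.interaction_sig_frac,
            "optimism": report.optimism,
            "c_original": report.c_original,
            "c_adjusted": report.c_adjusted,
            "c_median": report.c_median,
            "c_ci": list(report.c_ci),
            "n_resamples": report.n_resamples,
            "n_converged": report.n_converged,
            "seed": report.seed,
        }
        with open(out_dir / "internal_validation.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    if result.contrast is not None:
        c = result.contrast
        rows = []
        for lab, v, row_lo, row, row_hi in zip(
            c.dose_labels,
            c.dose_values,
            c.ci_low if c.ci_low is not None else [None] * len(c.dose_values),
            c.log_hr,
            c.ci_high if c.ci_high is not None else [None] * len(c.dose_values),
        ):
            for k, x in enumerate(c.density_grid_hu):
                rows.append(
                    {
                        "dose_ref": lab,
                        "dose_value": float(v),
                        "density_hu": float(x),
                        "log_hr": float(row[k]),
                        "ci_low": float(row_lo[k]) if row_lo is not None else np.nan,
                        "ci_high": float(row_hi[k]) if row_hi is not None else np.nan,
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / "contrast.csv", index=False)
    if result.stratification is not None:
        s = result.stratification
        frames = []
        for (stratum, group), df in s.curves.items():
            d = df.copy()
            d["dose_stratum"] = stratum
            d["density_group"] = group
            frames.append(d)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(out_dir / "km_curves.csv", index=False)
        with open(out_dir / "km_logrank.json", "w") as fh:
            json.dump(
                {
                    "density_cut_hu": s.density_cut_hu,
                    "dose_tertiles_gy": list(s.dose_tertiles_gy),
                    "logrank_p": s.logrank_p,
                },
                fh,
                indent=2,
            )


def likelihood_ratio_test_safe(full, reduced) -> float:
    from .survival import likelihood_ratio_test

    try:
        return likelihood_ratio_test(full, reduced).p_value
    except Exception:
        return float("nan")
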