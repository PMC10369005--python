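"""Cox-per-radius interaction scanning and region post-processing.

For every pair of (density annulus a, dose annulus b) the scan compares

    clinical + density(a) + dose(b) + density(a) * dose(b)
    clinical + density(a) + dose(b)

with a 1-df likelihood-ratio test, giving a p-value heat-map over the
annulus grid.  Cells with p below alpha form the significance mask; its
8-connected components become candidate regions, which must be at least
3 mm thick on both the density and dose axes (average thickness = area /
extent along the other axis) to survive the region-size multiple-testing
correction.  Retained regions are summarised per patient by averaging the
smoothed curves over the region's bounding box on each axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .survival import (
    clinical_design,
    endpoint_columns,
    fit_cox,
    likelihood_ratio_test,
)
from .errors import UsageError

__all__ = ["InteractionMap", "CandidateRegion", "scan", "extract_regions",
           "region_values", "candidate_model"]

DENSITY_SCALE_HU = 100.0


@dataclass
class InteractionMap:
    density_metric: str
    dose_metric: str
    endpoint: str
    p_values: np.ndarray  # (n_density_bins, n_dose_bins)
    converged: np.ndarray  # bool, same shape
    density_centers_mm: np.ndarray
    dose_centers_mm: np.ndarray
    alpha: float = 0.05

    @property
    def significance_mask(self) -> np.ndarray:
        return (self.p_values < self.alpha) & self.converged


@dataclass
class CandidateRegion:
    cells: np.ndarray  # boolean mask on the map grid
    density_interval_mm: tuple[float, float]
    dose_interval_mm: tuple[float, float]
    thickness_density_mm: float
    thickness_dose_mm: float
    density_metric: str = ""
    dose_metric: str = ""
    status: str = "candidate"  # below_size | unstable | no_Cindex_gain | retained
    min_p: float = np.nan
    patient_density_hu: np.ndarray | None = None
    patient_dose_gy: np.ndarray | None = None
    details: dict = field(default_factory=dict)


def _select_bins(centers: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
    lo, hi = rng
    return np.nonzero((centers > lo) & (centers < hi))[0]


def scan(
    curves: dict[str, np.ndarray],
    clinical: pd.DataFrame,
    density_centers: np.ndarray,
    dose_centers: np.ndarray,
    endpoint: str = "LR",
    density_metric: str = "density_p90",
    dose_metric: str = "dose_sd",
    density_range_mm: tuple[float, float] = (-5.0, 20.0),
    dose_range_mm: tuple[float, float] = (5.0, 20.0),
    alpha: float = 0.05,
    fill_fraction: dict | None = None,
    max_fill_fraction: float = 0.5,
) -> InteractionMap:
    """Build one interaction heat-map for a density/dose metric pair.

    ``curves[metric]`` is the (n_patients, n_bins) matrix of smoothed curve
    values on the stated bin centers.  Cells whose full model fails to
    converge get p = 1 and a convergence flag; more than 20% of such cells
    triggers a scan-level warning.

    ``fill_fraction[metric]`` gives, per annulus, the fraction of patients
    whose value there was imputed from a neighbouring annulus (empty
    annulus fill).  Annuli imputed for more than ``max_fill_fraction`` of
    patients carry no independent measurement — their values are copies of
    a neighbour — so no test is run there (cells flagged untested with
    p = 1).  Testing them would count the same evidence several times and
    manufacture cluster area for the region-size rule.
    """
    tcol, ecol = endpoint_columns(endpoint)
    time = clinical[tcol].to_numpy(dtype=float)
    event = clinical[ecol].to_numpy()
    base = clinical_design(clinical).to_numpy(dtype=float)
    n_clin = base.shape[1]

    d_idx = _select_bins(np.asarray(density_centers), density_range_mm)
    z_idx = _select_bins(np.asarray(dose_centers), dose_range_mm)
    dens = np.asarray(curves[density_metric], dtype=float)[:, d_idx] / DENSITY_SCALE_HU
    dose = np.asarray(curves[dose_metric], dtype=float)[:, z_idx]
    dens = dens - dens.mean(axis=0)
    dose = dose - dose.mean(axis=0)

    def _testable(metric, idx):
        if fill_fraction is None or metric not in fill_fraction:
            return np.ones(len(idx), dtype=bool)
        return np.asarray(fill_fraction[metric], dtype=float)[idx] <= max_fill_fraction

    d_ok = _testable(density_metric, d_idx)
    z_ok = _testable(dose_metric, z_idx)

    shape = (len(d_idx), len(z_idx))
    pvals = np.ones(shape)
    conv = np.zeros(shape, dtype=bool)
    warm_red = None
    for a in range(shape[0]):
        if not d_ok[a]:
            continue
        xa = dens[:, a]
        for b in range(shape[1]):
            if not z_ok[b]:
                continue
            zb = dose[:, b]
            X_red = np.column_stack([base, xa, zb])
            X_full = np.column_stack([X_red, xa * zb])
            try:
                red = fit_cox(X_red, time, event, warm_start=warm_red, compute_cindex=False)
                full = fit_cox(
                    X_full, time, event,
                    warm_start=np.append(red.coef, 0.0), compute_cindex=False,
                )
            except Exception:
                continue
            warm_red = red.coef
            if not (red.converged and full.converged):
                continue
            pvals[a, b] = likelihood_ratio_test(full, red).p_value
            conv[a, b] = True
    tested = np.outer(d_ok, z_ok)
    frac_bad = 1.0 - conv[tested].mean() if tested.any() else 1.0
    if frac_bad > 0.2:
        warnings.warn(
            f"{frac_bad:.0%} of scan cells failed to converge "
            f"({density_metric} x {dose_metric}, endpoint {endpoint})"
        )
    del n_clin
    return InteractionMap(
        density_metric=density_metric,
        dose_metric=dose_metric,
        endpoint=endpoint,
        p_values=pvals,
        converged=conv,
        density_centers_mm=np.asarray(density_centers)[d_idx],
        dose_centers_mm=np.asarray(dose_centers)[z_idx],
        alpha=alpha,
    )


def extract_regions(
    imap: InteractionMap,
    min_thickness_mm: float = 3.0,
    thickness_method: str = "area_over_extent",
) -> list[CandidateRegion]:
    """Connected significant components with the 3 mm size filter applied.

    Components are 8-connected.  With 1 mm cells the average thickness
    along one axis is the component area divided by its extent along the
    other axis (``thickness_method='bounding_extent'`` uses the bounding
    box extents instead).  Components thinner than ``min_thickness_mm`` on
    either axis are marked ``below_size``; the rest stay candidates.
    """
    mask = imap.significance_mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    regions: list[CandidateRegion] = []
    for k in range(1, n + 1):
        cells = labels == k
        rows = np.nonzero(cells.any(axis=1))[0]
        cols = np.nonzero(cells.any(axis=0))[0]
        extent_d = rows[-1] - rows[0] + 1  # density-axis extent, mm
        extent_z = cols[-1] - cols[0] + 1
        area = float(cells.sum())
        if thickness_method == "area_over_extent":
            t_density = area / extent_z
            t_dose = area / extent_d
        elif thickness_method == "bounding_extent":
            t_density, t_dose = float(extent_d), float(extent_z)
        else:
            raise UsageError(f"unknown thickness method {thickness_method!r}")
        region = CandidateRegion(
            cells=cells,
            density_interval_mm=(
                float(imap.density_centers_mm[rows[0]] - 0.5),
                float(imap.density_centers_mm[rows[-1]] + 0.5),
            ),
            dose_interval_mm=(
                float(imap.dose_centers_mm[cols[0]] - 0.5),
                float(imap.dose_centers_mm[cols[-1]] + 0.5),
            ),
            thickness_density_mm=t_density,
            thickness_dose_mm=t_dose,
            density_metric=imap.density_metric,
            dose_metric=imap.dose_metric,
            min_p=float(imap.p_values[cells].min()),
        )
        if min(t_density, t_dose) < min_thickness_mm:
            region.status = "below_size"
        regions.append(region)
    return regions


def region_values(
    region: CandidateRegion,
    curves: dict[str, np.ndarray],
    density_centers: np.ndarray,
    dose_centers: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient (density HU, dose Gy): curve means over the region box."""
    d_sel = _select_bins(np.asarray(density_centers), region.density_interval_mm)
    z_sel = _select_bins(np.asarray(dose_centers), region.dose_interval_mm)
    if len(d_sel) == 0 or len(z_sel) == 0:
        raise UsageError("region box lies outside the curve domains")
    dens = np.asarray(curves[region.density_metric], dtype=float)[:, d_sel].mean(axis=1)
    dose = np.asarray(curves[region.dose_metric], dtype=float)[:, z_sel].mean(axis=1)
    region.patient_density_hu = dens
    region.patient_dose_gy = dose
    return dens, dose


def candidate_model(
    density_hu: np.ndarray,
    dose_gy: np.ndarray,
    clinical: pd.DataFrame,
    endpoint: str = "LR",
):
    """Overall Cox fits for a candidate region, without / with interaction.

    Terms: the clinical covariates plus the region's density (per 100 HU)
    and dose values, and for the full model their product.  The reduced
    model is the exact nested sub-model (identical preprocessing).
    """
    tcol, ecol = endpoint_columns(endpoint)
    time = clinical[tcol].to_numpy(dtype=float)
    event = clinical[ecol].to_numpy()
    design = clinical_design(clinical)
    x = np.asarray(density_hu, dtype=float) / DENSITY_SCALE_HU
    z = np.asarray(dose_gy, dtype=float)
    design = design.copy()
    design["density_100hu"] = x - x.mean()
    design["dose_gy"] = z - z.mean()
    reduced = fit_cox(design, time, event)
    full_design = design.copy()
    full_design["density_x_dose"] = design["density_100hu"] * design["dose_gy"]
    full = fit_cox(full_design, time, event, warm_start=np.append(reduced.coef, 0.0))
    return reduced, full
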