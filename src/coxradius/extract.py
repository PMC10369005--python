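"""Per-patient feature extraction: volumes in, radial curves + dose stats out.

Composes the primitives in :mod:`coxradius.radial` in the fixed order of
the method: signed distance from the GTV, respiratory blurring of the
physical dose along the motion trajectory, EQD2 conversion (blur first,
then EQD2), density cross-histogram restricted to lung, smoothed density
and dose summary curves, and GTV/PTV dose statistics (GTV on the blurred
EQD2 dose, PTV on the planned EQD2 dose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import radial

__all__ = ["PatientFeatures", "extract_patient"]

DENSITY_METRICS = ("density_mean", "density_p90", "density_sd")
DOSE_METRICS = ("dose_sd", "dose_frac_lt30", "dose_mean")


@dataclass
class PatientFeatures:
    curves: dict[str, radial.RadialCurve]
    gtv_stats: radial.DoseStatistics
    ptv_stats: radial.DoseStatistics
    distance: radial.DistanceMap


def extract_patient(
    density: np.ndarray,
    dose_physical: np.ndarray,
    gtv: np.ndarray,
    lung: np.ndarray,
    spacing,
    n_fractions: int,
    motion_cm: float,
    body_mask: np.ndarray | None = None,
    alpha_beta_gy: float = 10.0,
    sigma_mm: float = radial.SMOOTH_SIGMA_MM,
    dose_range_mm=radial.DOSE_RANGE_MM,
    eqd2_threshold_gy: float = 30.0,
    ptv_margin_mm: float = 5.0,
    distance: radial.DistanceMap | None = None,
    n_phases: int = 10,
) -> PatientFeatures:
    """All radial features for one patient.

    ``body_mask`` defaults to the full grid (no body-contour crop).  A
    precomputed distance map can be passed to avoid recomputing it.
    """
    spacing = tuple(np.broadcast_to(np.asarray(spacing, dtype=float), (3,)))
    if distance is None:
        distance = radial.signed_distance(gtv, spacing)
    if body_mask is None:
        body_mask = np.ones_like(gtv, dtype=bool)

    trajectory = radial.sinusoidal_trajectory(motion_cm, n_phases=n_phases)
    blurred = radial.blur_dose(dose_physical, trajectory, spacing)
    blurred_eqd2 = radial.eqd2(blurred, n_fractions, alpha_beta_gy)
    planned_eqd2 = radial.eqd2(dose_physical, n_fractions, alpha_beta_gy)

    hist = radial.cross_histogram(density, distance, lung)
    curves = radial.density_curves(hist, sigma_mm=sigma_mm)
    curves.update(
        radial.dose_curves(
            blurred_eqd2,
            distance,
            body_mask,
            distance_range_mm=dose_range_mm,
            threshold_gy=eqd2_threshold_gy,
            sigma_mm=sigma_mm,
        )
    )
    gtv_stats = radial.structure_dose_stats(blurred_eqd2, gtv, "GTV")
    ptv = distance.values <= ptv_margin_mm
    ptv_stats = radial.structure_dose_stats(planned_eqd2, ptv, "PTV")
    return PatientFeatures(
        curves=curves, gtv_stats=gtv_stats, ptv_stats=ptv_stats, distance=distance
    )
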