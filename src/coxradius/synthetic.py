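"""Synthetic lung-SABR cohorts with planted dose-density interactions.

Each patient is a quasi-spherical dense tumour (GTV, ~0 HU) inside noisy
lung parenchyma (~-800 HU), optionally surrounded by a peritumoral density
halo whose HU offset varies between patients; a SABR-like plan delivering
the prescription inside the PTV (GTV + 5 mm) with smooth in-target
heterogeneity and exponential radial fall-off; a sinusoidal cranio-caudal
respiratory trajectory; and clinical covariates (age, sex, lobe, tumour
volume, motion amplitude).

Outcomes are drawn from an exponential-baseline proportional-hazards model
whose linear predictor contains the clinical covariates plus a density
feature, a dose feature, and their product, where the two features are
averages of the radial curves over configurable planted intervals.  The
curves entering the hazard are computed by :mod:`coxradius.radial` on the
generated volumes themselves, so recovering the planted interaction
exercises the full extraction + scanning pipeline, not a shortcut.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy`` Generator: the same config yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import radial
from .config import OutcomeModel, SimulationConfig
from .errors import DataError, ParameterError, SizingError
from .extract import extract_patient

__all__ = ["SyntheticPatient", "Cohort", "generate_geometry", "generate_dose",
           "sample_outcomes", "simulate_cohort"]

N_PHASES = 10


@dataclass
class SyntheticPatient:
    patient_id: str
    density: np.ndarray
    dose: np.ndarray  # planned physical dose, Gy
    gtv: np.ndarray
    lung: np.ndarray
    spacing: tuple[float, float, float]
    motion_cm: float
    trajectory_mm: np.ndarray
    covariates: dict


@dataclass
class Cohort:
    """In-memory cohort: clinical table + stacked radial curves.

    ``curves[metric]`` is an (n_patients, n_bins) array of smoothed curve
    values; ``truth`` holds the feature values that entered the hazard.
    Volumes are kept only when ``keep_volumes`` was requested.
    """

    config: SimulationConfig
    clinical: pd.DataFrame
    curves: dict[str, np.ndarray]
    # per metric: (n_patients, n_bins) flag of annuli imputed from a
    # neighbour because the annulus held no voxels for that patient
    filled: dict[str, np.ndarray]
    density_centers: np.ndarray
    dose_centers: np.ndarray
    truth: pd.DataFrame
    dose_stats: pd.DataFrame
    patients: list[SyntheticPatient] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return len(self.clinical)


def _check_grid(config: SimulationConfig, max_semiaxis_mm: float) -> None:
    half_extent = np.array(config.grid_shape) * config.voxel_spacing_mm / 2.0
    needed = max_semiaxis_mm + config.required_margin_mm
    if np.any(needed > half_extent):
        raise SizingError(
            f"grid half-extent {half_extent.min():.0f} mm cannot hold a "
            f"{max_semiaxis_mm:.0f} mm tumour plus the {config.required_margin_mm:.0f} mm "
            f"margin; need at least {needed:.0f} mm per half-axis"
        )


def generate_geometry(config: SimulationConfig, rng: np.random.Generator):
    """One patient's density volume, GTV mask and lung mask.

    Returns ``(density, gtv, lung, dist)`` where ``dist`` is the signed
    distance map from the GTV surface (reused downstream).  The dense
    tumour core is a randomly-oriented ellipsoid with semi-axes within
    +/-15% of the drawn radius; the delineated GTV contour over-covers the
    core by ``lung.contour_margin_mm``, so the lung mask (core complement)
    keeps a thin parenchyma rim just inside the contour and density remains
    measurable at small negative distances from the GTV surface.  The halo
    adds a patient-level HU offset to the lung shell within a per-patient
    width of the contour.
    """
    spacing = config.voxel_spacing_mm
    shape = tuple(config.grid_shape)
    radius = rng.uniform(*config.tumor_radius_range_mm)
    axes = radius * rng.uniform(0.85, 1.15, size=3)
    _check_grid(config, float(axes.max()))

    center = (np.array(shape) - 1) / 2.0 + rng.uniform(-1.0, 1.0, size=3)
    grids = np.meshgrid(*(np.arange(s, dtype=np.float32) for s in shape), indexing="ij")
    core_axes = np.maximum(axes - config.lung.contour_margin_mm, 0.5 * spacing)
    u2_gtv = sum(((g - c) * spacing / a) ** 2 for g, c, a in zip(grids, center, axes))
    u2_core = sum(((g - c) * spacing / a) ** 2 for g, c, a in zip(grids, center, core_axes))
    gtv = u2_gtv <= 1.0
    core = u2_core <= 1.0
    lung = ~core

    density = np.where(
        core, np.float32(config.lung.tumor_core_hu), np.float32(config.lung.mean_hu)
    ).astype(np.float32)
    density += rng.normal(0.0, config.lung.noise_sd_hu, size=shape).astype(np.float32)
    if config.lung.texture_sd_hu > 0:
        from scipy.ndimage import gaussian_filter

        texture = gaussian_filter(
            rng.standard_normal(shape).astype(np.float32),
            sigma=config.lung.texture_corr_mm / spacing,
        )
        density += np.float32(config.lung.texture_sd_hu / texture.std()) * texture

    dist = radial.signed_distance(gtv, (spacing,) * 3)
    if config.halo.width_mm > 0:
        offset = config.halo.mean_offset_hu + config.halo.patient_sd_hu * rng.standard_normal()
        width = config.halo.width_mm * rng.uniform(
            1.0 - config.halo.width_rel_spread, 1.0 + config.halo.width_rel_spread
        )
        shell = lung & (dist.values >= 0.0) & (dist.values < width)
        density[shell] += np.float32(offset)
    return density, gtv, lung, dist


def generate_dose(
    config: SimulationConfig,
    gtv: np.ndarray,
    rng: np.random.Generator,
    dist: radial.DistanceMap | None = None,
):
    """SABR-like planned physical dose for one patient.

    Prescription-level dose inside the PTV (GTV + 5 mm, via the distance
    map) plus a smooth zero-mean heterogeneity field normalised to the
    configured in-PTV SD; outside, both decay as exp(-d / fall-off scale).
    The per-patient heterogeneity amplitude and fall-off scale are drawn
    uniformly within the configured relative spreads.
    """
    if not np.any(gtv):
        raise ParameterError("GTV mask is empty")
    plan = config.dose_plan
    if plan.falloff_scale_mm <= 0:
        raise ParameterError("fall-off scale must be positive")
    spacing = config.voxel_spacing_mm
    if dist is None:
        dist = radial.signed_distance(gtv, (spacing,) * 3)

    falloff = plan.falloff_scale_mm * rng.uniform(
        1.0 - plan.falloff_rel_spread, 1.0 + plan.falloff_rel_spread
    )
    het_sd = plan.heterogeneity_sd_gy * rng.uniform(
        1.0 - plan.heterogeneity_rel_spread, 1.0 + plan.heterogeneity_rel_spread
    )

    d_out = np.maximum(dist.values - plan.ptv_margin_mm, 0.0)
    with np.errstate(over="ignore"):
        envelope = np.exp(-d_out / falloff) if np.isfinite(falloff) else np.ones_like(d_out)
    dose = plan.prescription_gy * envelope

    if het_sd > 0:
        from scipy.ndimage import gaussian_filter

        noise = rng.standard_normal(size=gtv.shape).astype(np.float32)
        fieldv = gaussian_filter(noise, sigma=plan.heterogeneity_corr_mm / spacing)
        ptv = dist.values <= plan.ptv_margin_mm
        sd_in = fieldv[ptv].std()
        if sd_in > 0:
            dose = dose + het_sd * (fieldv / sd_in) * envelope
    return np.maximum(dose, 0.0)


def sample_outcomes(
    model: OutcomeModel,
    censoring,
    features: pd.DataFrame,
    rng: np.random.Generator,
):
    """Draw (time, event) per patient from the proportional-hazards model.

    ``features`` needs columns ``age``, ``sex_male``, ``lobe_upper``,
    ``motion_cm``, ``ln_volume``, ``density_hu`` and ``dose_gy``.  Density
    is rescaled to 100 HU units; continuous features are centered at the
    cohort mean (binaries at their reference level) so the baseline rate
    describes a typical reference patient.  Event times are exponential
    with rate ``baseline * exp(lp)``; censoring is the minimum of the
    administrative horizon and an independent exponential drop-out draw.
    """
    if censoring.horizon_months <= 0:
        raise ParameterError("administrative horizon must be positive")
    n = len(features)

    def centered(col):
        v = features[col].to_numpy(dtype=float)
        return v - v.mean()

    x_d = centered("density_hu") / 100.0
    z = centered("dose_gy")
    lp = (
        model.coef_age * centered("age")
        + model.coef_sex_male * features["sex_male"].to_numpy(dtype=float)
        + model.coef_lobe_upper * features["lobe_upper"].to_numpy(dtype=float)
        + model.coef_motion * centered("motion_cm")
        + model.coef_ln_volume * centered("ln_volume")
        + model.coef_density * x_d
        + model.coef_dose * z
        + model.coef_interaction * x_d * z
    )
    bad = ~np.isfinite(lp)
    if bad.any():
        raise DataError(f"non-finite linear predictor for patient index {int(np.nonzero(bad)[0][0])}")
    rate = model.baseline_rate_per_month * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_cens = np.full(n, censoring.horizon_months)
    if censoring.random_rate_per_month > 0:
        t_cens = np.minimum(t_cens, rng.exponential(1.0 / censoring.random_rate_per_month, size=n))
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return time, event.astype(int)


def _interval_mean(curve: np.ndarray, centers: np.ndarray, interval) -> float:
    lo, hi = interval
    sel = (centers > lo) & (centers < hi)
    if not sel.any():
        raise ParameterError(f"planted interval {interval} covers no annuli")
    return float(curve[sel].mean())


def _sample_covariates(config: SimulationConfig, rng: np.random.Generator) -> dict:
    return {
        "age": float(np.clip(rng.normal(75.0, 8.0), 45.0, 92.0)),
        "sex": "male" if rng.random() < 0.49 else "female",
        "lobe": "upper" if rng.random() < 0.65 else "lower",
        "motion_cm": float(rng.uniform(*config.motion_amplitude_range_cm)),
    }


def simulate_cohort(
    config: SimulationConfig,
    keep_volumes: bool = False,
    smoothing_sigma_mm: float = radial.SMOOTH_SIGMA_MM,
) -> Cohort:
    """Generate a full cohort: volumes -> radial curves -> outcomes.

    Volumes are processed one patient at a time and discarded unless
    ``keep_volumes`` (memory stays flat in cohort size).  Local relapse
    outcomes come from ``config.outcome``; regional-failure outcomes from
    ``config.rf_outcome`` when given, otherwise from the same clinical
    coefficients with all imaging terms zeroed.
    """
    rng = np.random.default_rng(config.seed)
    spacing3 = (config.voxel_spacing_mm,) * 3
    plan = config.dose_plan

    clin_rows, truth_rows, stats_rows = [], [], []
    curve_rows: dict[str, list[np.ndarray]] = {}
    filled_rows: dict[str, list[np.ndarray]] = {}
    patients: list[SyntheticPatient] = []
    density_centers = dose_centers = None

    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        density, gtv, lung, dist = generate_geometry(config, rng)
        dose = generate_dose(config, gtv, rng, dist=dist)
        cov = _sample_covariates(config, rng)
        feats = extract_patient(
            density,
            dose,
            gtv,
            lung,
            spacing3,
            plan.n_fractions,
            cov["motion_cm"],
            sigma_mm=smoothing_sigma_mm,
            ptv_margin_mm=plan.ptv_margin_mm,
            distance=dist,
            n_phases=N_PHASES,
        )
        dcurves = feats.curves
        for name, c in dcurves.items():
            curve_rows.setdefault(name, []).append(c.values)
            flags = np.zeros(len(c.values), dtype=bool)
            flags[c.filled_bins] = True
            filled_rows.setdefault(name, []).append(flags)
        density_centers = dcurves["density_mean"].distance_mm
        dose_centers = dcurves["dose_sd"].distance_mm

        stats_rows.append(
            {
                "patient_id": pid,
                **{f"GTV_{k}": getattr(feats.gtv_stats, k) for k in ("mean", "max", "min", "sd")},
                **{f"PTV_{k}": getattr(feats.ptv_stats, k) for k in ("mean", "max", "min", "sd")},
            }
        )

        volume_cc = float(gtv.sum()) * config.voxel_spacing_mm**3 / 1000.0
        clin_rows.append({"patient_id": pid, "tumor_volume_cc": volume_cc, **cov})

        om = config.outcome
        truth_rows.append(
            {
                "patient_id": pid,
                "density_hu": _interval_mean(
                    dcurves[om.density_metric].values, density_centers, om.density_interval_mm
                ),
                "dose_gy": _interval_mean(
                    dcurves[om.dose_metric].values, dose_centers, om.dose_interval_mm
                ),
            }
        )
        if keep_volumes:
            patients.append(
                SyntheticPatient(
                    patient_id=pid,
                    density=density,
                    dose=dose,
                    gtv=gtv,
                    lung=lung,
                    spacing=spacing3,
                    motion_cm=cov["motion_cm"],
                    trajectory_mm=radial.sinusoidal_trajectory(cov["motion_cm"], n_phases=N_PHASES),
                    covariates=cov,
                )
            )

    clinical = pd.DataFrame(clin_rows)
    truth = pd.DataFrame(truth_rows)
    features = pd.DataFrame(
        {
            "age": clinical["age"],
            "sex_male": (clinical["sex"] == "male").astype(float),
            "lobe_upper": (clinical["lobe"] == "upper").astype(float),
            "motion_cm": clinical["motion_cm"],
            "ln_volume": np.log(clinical["tumor_volume_cc"]),
            "density_hu": truth["density_hu"],
            "dose_gy": truth["dose_gy"],
        }
    )
    time_lr, event_lr = sample_outcomes(config.outcome, config.censoring, features, rng)
    rf_model = config.rf_outcome
    if rf_model is None:
        from dataclasses import replace

        rf_model = replace(config.outcome, coef_density=0.0, coef_dose=0.0, coef_interaction=0.0)
    time_rf, event_rf = sample_outcomes(rf_model, config.censoring, features, rng)
    clinical["time_lr"] = time_lr
    clinical["event_lr"] = event_lr
    clinical["time_rf"] = time_rf
    clinical["event_rf"] = event_rf

    curves = {k: np.vstack(v) for k, v in curve_rows.items()}
    filled = {k: np.vstack(v) for k, v in filled_rows.items()}
    return Cohort(
        config=config,
        clinical=clinical,
        curves=curves,
        filled=filled,
        density_centers=np.asarray(density_centers),
        dose_centers=np.asarray(dose_centers),
        truth=truth,
        dose_stats=pd.DataFrame(stats_rows),
        patients=patients,
    )
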