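"""Configuration objects for the synthetic cohort and the analysis pipeline.

All physical quantities carry their unit in the field name (mm, cm, Gy, HU,
months).  Defaults describe a lung SABR setting: a 60 Gy / 5 fraction
prescription, tumours of a few cc inside lung parenchyma near -800 HU, and
respiratory motion amplitudes below ~1.2 cm.  Every default is plain data and
can be overridden from a YAML config file (see :mod:`coxradius.cli`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from .errors import ParameterError

__all__ = [
    "HaloConfig",
    "LungConfig",
    "DosePlan",
    "OutcomeModel",
    "CensoringConfig",
    "SimulationConfig",
    "ScanSettings",
    "config_to_dict",
    "config_from_dict",
]


@dataclass
class HaloConfig:
    """Peritumoral density halo: a shell of elevated HU outside the GTV.

    ``patient_sd_hu`` is the between-patient spread of the halo offset; it is
    what makes peritumor density an informative per-patient biomarker.
    """

    width_mm: float = 3.0
    mean_offset_hu: float = 150.0
    patient_sd_hu: float = 100.0
    width_rel_spread: float = 0.33


@dataclass
class LungConfig:
    """Lung parenchyma background density."""

    mean_hu: float = -800.0
    noise_sd_hu: float = 40.0
    # correlated texture (vessels, septa, gravity gradients): without it the
    # parenchyma averages to its mean inside every annulus and the curves
    # collapse onto a handful of patient-level factors
    texture_sd_hu: float = 40.0
    texture_corr_mm: float = 5.0
    tumor_core_hu: float = 0.0
    # The delineated GTV over-covers the dense core by this margin, so a thin
    # parenchyma rim just inside the contour still counts as lung (density at
    # small negative distances stays measurable, as in real segmentations).
    contour_margin_mm: float = 2.0


@dataclass
class DosePlan:
    """SABR-like plan: flat-ish dose in the PTV, exponential radial fall-off.

    ``heterogeneity_sd_gy`` is the in-PTV dose SD of a smooth random field
    (conformal SABR plans deliberately allow in-target heterogeneity);
    ``falloff_scale_mm`` is the e-folding length of the dose outside the PTV.
    The two ``*_rel_spread`` values give each patient an individual
    heterogeneity amplitude and fall-off scale drawn uniformly within
    ``value * (1 +/- spread)``, which is what creates between-patient variance
    in the incidental-dose metrics.
    """

    prescription_gy: float = 60.0
    n_fractions: int = 5
    heterogeneity_sd_gy: float = 4.0
    falloff_scale_mm: float = 8.0
    heterogeneity_rel_spread: float = 0.5
    falloff_rel_spread: float = 0.2
    heterogeneity_corr_mm: float = 6.0
    ptv_margin_mm: float = 5.0


@dataclass
class OutcomeModel:
    """Proportional-hazards generator for one endpoint.

    Coefficients are log hazard ratios per unit of the (centered) covariate:
    age in years, motion in cm, ln(tumour volume in cc), density in 100 HU,
    dose in Gy, and their product for the interaction.  The density and dose
    features are annulus averages of the radial curves over the planted
    intervals, computed by :mod:`coxradius.radial` on the generated volumes so
    that recoverability is a property of the whole pipeline.
    """

    baseline_rate_per_month: float = 0.01
    coef_age: float = 0.01
    coef_sex_male: float = 0.2
    coef_lobe_upper: float = 0.3
    coef_motion: float = 0.2
    # per e-fold of tumour volume; hazard ratio ~3 per ln(cc) is the kind of
    # volume effect reported for local relapse after lung SABR
    coef_ln_volume: float = 1.1
    # Density and interaction defaults are tied: with centered features the
    # density log-HR at dose variability z is coef_density +
    # coef_interaction * (z - mean z), so coef_density ~ 1.6 * coef_interaction
    # makes the density effect vanish in the lowest dose-SD tertile and
    # roughly double in the highest -- the signature dose-density pattern
    # this method exists to detect.
    coef_density: float = 1.6
    coef_dose: float = 0.1
    coef_interaction: float = 1.0
    density_metric: str = "density_p90"
    dose_metric: str = "dose_sd"
    density_interval_mm: tuple[float, float] = (0.0, 3.0)
    dose_interval_mm: tuple[float, float] = (5.0, 16.0)


@dataclass
class CensoringConfig:
    """Administrative horizon plus independent random (drop-out) censoring."""

    horizon_months: float = 60.0
    random_rate_per_month: float = 0.005


@dataclass
class SimulationConfig:
    n_patients: int = 150
    voxel_spacing_mm: float = 2.0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    tumor_radius_range_mm: tuple[float, float] = (6.0, 14.0)
    motion_amplitude_range_cm: tuple[float, float] = (0.0, 1.2)
    required_margin_mm: float = 20.0
    halo: HaloConfig = field(default_factory=HaloConfig)
    lung: LungConfig = field(default_factory=LungConfig)
    dose_plan: DosePlan = field(default_factory=DosePlan)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    # Regional failure is generated from the clinical covariates only (no
    # dose/density terms) unless a dedicated model is supplied.
    rf_outcome: OutcomeModel | None = None
    censoring: CensoringConfig = field(default_factory=CensoringConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ParameterError("n_patients must be >= 2")
        if self.voxel_spacing_mm <= 0:
            raise ParameterError("voxel_spacing_mm must be positive")
        lo, hi = self.tumor_radius_range_mm
        if lo <= 0 or hi < lo:
            raise ParameterError("tumor_radius_range_mm must be positive and ordered")
        if self.halo.width_mm < 0:
            raise ParameterError("halo width must be >= 0")
        if self.dose_plan.prescription_gy <= 0:
            raise ParameterError("prescription must be positive")
        if self.dose_plan.n_fractions < 1:
            raise ParameterError("n_fractions must be >= 1")
        if self.dose_plan.falloff_scale_mm <= 0:
            raise ParameterError("falloff_scale_mm must be positive")
        lo, hi = self.motion_amplitude_range_cm
        if lo < 0 or hi < lo:
            raise ParameterError("motion_amplitude_range_cm must be >= 0 and ordered")


@dataclass
class ScanSettings:
    """Fixed constants of the radial analysis.

    Defaults are the canonical settings of the method: density annuli from
    0.5 cm inside to 2 cm outside the GTV, dose annuli 0.5-2 cm outside
    (configurable up to 4 cm), 1 mm bins, Gaussian smoothing sigma = 1.5 mm,
    EQD2 with alpha/beta = 10 Gy, a 30 Gy EQD2 threshold for the low-dose
    fraction, alpha = 0.05 significance, a 3 mm minimum region thickness, and
    500 bootstrap resamples.
    """

    endpoint: str = "LR"
    density_metrics: tuple[str, ...] = ("density_mean", "density_p90", "density_sd")
    dose_metrics: tuple[str, ...] = ("dose_sd", "dose_frac_lt30")
    density_range_mm: tuple[float, float] = (-5.0, 20.0)
    dose_range_mm: tuple[float, float] = (5.0, 20.0)
    dose_extraction_range_mm: tuple[float, float] = (5.0, 40.0)
    alpha: float = 0.05
    smoothing_sigma_mm: float = 1.5
    alpha_beta_gy: float = 10.0
    eqd2_threshold_gy: float = 30.0
    min_thickness_mm: float = 3.0
    n_bootstrap: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not self.density_metrics:
            raise ParameterError("density_metrics must not be empty")
        if not self.dose_metrics:
            raise ParameterError("dose_metrics must not be empty")
        if self.endpoint not in ("LR", "RF"):
            raise ParameterError(f"unknown endpoint {self.endpoint!r}")
        if not (0 < self.alpha <= 1):
            raise ParameterError("alpha must be in (0, 1]")
        if self.n_bootstrap < 1:
            raise ParameterError("n_bootstrap must be >= 1")


def config_to_dict(cfg) -> dict:
    """Dataclass config -> plain JSON-serialisable dict."""
    return asdict(cfg)


def _build(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        sub = f.type if isinstance(f.type, type) else None
        if value is None:
            kwargs[f.name] = None
        elif f.name in _NESTED.get(cls, {}):
            kwargs[f.name] = _build(_NESTED[cls][f.name], value)
        elif isinstance(value, list):
            kwargs[f.name] = tuple(value)
        else:
            kwargs[f.name] = value
        del sub
    return cls(**kwargs)


_NESTED = {
    SimulationConfig: {
        "halo": HaloConfig,
        "lung": LungConfig,
        "dose_plan": DosePlan,
        "outcome": OutcomeModel,
        "rf_outcome": OutcomeModel,
        "censoring": CensoringConfig,
    },
    OutcomeModel: {},
}


def config_from_dict(cls, data: dict):
    """Rebuild a config dataclass from a dict (e.g. parsed YAML/JSON)."""
    if not is_dataclass(cls):
        raise TypeError(f"{cls} is not a config dataclass")
    return _build(cls, data)


def dump_config(cfg, path) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(cfg), fh, indent=2)


def load_config(cls, path):
    with open(path) as fh:
        return config_from_dict(cls, json.load(fh))
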