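"""Radial feature extraction around a tumour volume.

Everything here works on co-registered 3D arrays with a known voxel spacing:

* signed Euclidean distance from the GTV surface (negative inside),
* EQD2 conversion of a physical dose volume,
* respiratory blurring of the dose by averaging over a motion trajectory,
* 2D cross-histograms of density vs distance restricted to lung,
* smoothed per-annulus summary curves for density (mean, 90th percentile,
  SD) and dose (SD, fraction of volume below an EQD2 threshold, mean),
* simple structure dose statistics (mean/max/min/SD inside a mask).

Annuli are half-open 1 mm distance bins ``[k, k+1)`` sampled at voxel
centers.  Density curves live on [-5, 20) mm, dose curves on [5, 40) mm by
default.  Curves are smoothed with a normalized Gaussian (sigma = 1.5 mm,
reflective boundaries) because annulus thickness is below typical slice
thickness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError, UsageError

__all__ = [
    "DistanceMap",
    "CrossHistogram",
    "RadialCurve",
    "DoseStatistics",
    "signed_distance",
    "eqd2",
    "sinusoidal_trajectory",
    "blur_dose",
    "cross_histogram",
    "density_curves",
    "dose_curves",
    "structure_dose_stats",
    "smooth_curve",
    "weighted_percentile",
]

DENSITY_RANGE_MM = (-5.0, 20.0)
DOSE_RANGE_MM = (5.0, 40.0)
DENSITY_BIN_HU = 10.0
DENSITY_HU_RANGE = (-1024.0, 200.0)
SMOOTH_SIGMA_MM = 1.5


@dataclass
class DistanceMap:
    """Per-voxel signed Euclidean distance (mm) from the GTV surface."""

    values: np.ndarray
    spacing: tuple[float, float, float]


@dataclass
class CrossHistogram:
    """Counts over (density bin x 1 mm distance bin), lung voxels only."""

    counts: np.ndarray  # (n_density_bins, n_distance_bins)
    density_edges: np.ndarray
    distance_edges: np.ndarray

    @property
    def density_centers(self) -> np.ndarray:
        return 0.5 * (self.density_edges[:-1] + self.density_edges[1:])

    @property
    def distance_centers(self) -> np.ndarray:
        return 0.5 * (self.distance_edges[:-1] + self.distance_edges[1:])


@dataclass
class RadialCurve:
    """One per-annulus summary statistic as a function of distance."""

    metric: str
    distance_mm: np.ndarray
    values: np.ndarray
    sigma_mm: float
    filled_bins: list[int] = field(default_factory=list)


@dataclass
class DoseStatistics:
    structure: str
    mean: float
    max: float
    min: float
    sd: float


def signed_distance(mask: np.ndarray, spacing) -> DistanceMap:
    """Signed Euclidean distance (mm) from the surface of ``mask``.

    Negative inside the mask.  The surface is taken to lie half a voxel
    beyond the outermost mask voxel centers, so boundary voxels sit within
    half a voxel of zero.  Anisotropic spacing is honoured via the EDT
    sampling argument.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (mask.ndim,))
    if np.any(spacing <= 0):
        raise ParameterError("voxel spacing must be positive")
    if not mask.any():
        raise GeometryError("empty mask: signed distance undefined")
    if mask.all():
        raise GeometryError("mask fills the whole grid: no surface exists")
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    # inside distances only matter on mask voxels, whose nearest background
    # voxel lies within one voxel of the mask bounding box: crop for speed
    slices = ndimage.find_objects(mask.astype(np.uint8))[0]
    slices = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, n)) for s, n in zip(slices, mask.shape)
    )
    d_in = np.zeros(mask.shape)
    d_in[slices] = ndimage.distance_transform_edt(mask[slices], sampling=spacing)
    half = 0.5 * float(spacing.min())
    values = np.where(mask, -(d_in - half), d_out - half)
    return DistanceMap(values=values, spacing=tuple(spacing))


def eqd2(dose: np.ndarray, n_fractions: int, alpha_beta: float = 10.0) -> np.ndarray:
    """Convert a total physical dose volume to EQD2 under the LQ model.

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta) with d = D / n the dose
    per fraction.  With alpha/beta = 10 Gy, 60 Gy in 5 fractions maps to
    110 Gy and 50 Gy in 5 fractions to ~83.3 Gy.
    """
    if alpha_beta <= 0:
        raise ParameterError("alpha/beta must be positive")
    if n_fractions < 1:
        raise ParameterError("n_fractions must be >= 1")
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ParameterError("dose must be non-negative")
    return dose * (dose / n_fractions + alpha_beta) / (2.0 + alpha_beta)


def sinusoidal_trajectory(amplitude_cm: float, n_phases: int = 10, axis: int = 0) -> np.ndarray:
    """Cranio-caudal respiratory trajectory sampled at equal time phases.

    ``amplitude_cm`` is the peak-to-peak motion amplitude.  Returns an
    (n_phases, 3) array of displacements in mm; equal time sampling of the
    sinusoid reproduces the end-exhale-weighted dwell-time distribution.
    """
    if amplitude_cm < 0:
        raise ParameterError("amplitude must be >= 0")
    t = np.arange(n_phases) / n_phases
    disp = np.zeros((n_phases, 3))
    disp[:, axis] = 0.5 * amplitude_cm * 10.0 * np.cos(2.0 * np.pi * t)
    return disp


def _shift_axis(volume: np.ndarray, shift_vox: float, axis: int) -> np.ndarray:
    """Linear-interpolation shift along one axis with edge replication.

    ``out[i] = in[i + shift_vox]`` along ``axis`` (sampling the input at the
    displaced position), matching the blur convention below.
    """
    n = volume.shape[axis]
    idx = np.arange(n) + shift_vox
    lo = np.clip(np.floor(idx).astype(int), 0, n - 1)
    hi = np.clip(lo + 1, 0, n - 1)
    frac = np.clip(idx - np.floor(idx), 0.0, 1.0)
    take_lo = np.take(volume, lo, axis=axis)
    take_hi = np.take(volume, hi, axis=axis)
    shape = [1] * volume.ndim
    shape[axis] = n
    frac = frac.reshape(shape)
    return take_lo * (1.0 - frac) + take_hi * frac


def blur_dose(dose: np.ndarray, trajectory_mm: np.ndarray, spacing) -> np.ndarray:
    """Respiratory-blurred dose: equal-weight average over trajectory phases.

    ``blurred(x) = mean_k dose(x + delta_k)`` with linear interpolation and
    edge replication.  Blurring is applied to the *physical* dose; EQD2
    conversion comes after.
    """
    dose = np.asarray(dose, dtype=float)
    trajectory_mm = np.atleast_2d(np.asarray(trajectory_mm, dtype=float))
    if trajectory_mm.shape[1] != dose.ndim:
        raise UsageError("trajectory must supply one displacement per axis")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (dose.ndim,))
    if not trajectory_mm.any():
        return dose.copy()
    shifts_vox = trajectory_mm / spacing
    if np.any(np.abs(shifts_vox) >= np.asarray(dose.shape)):
        raise GeometryError(
            "trajectory displacement exceeds the grid extent; "
            "enlarge the grid or reduce the amplitude"
        )
    out = np.zeros_like(dose)
    for shift in shifts_vox:
        moving_axes = np.nonzero(shift != 0)[0]
        phase = dose
        for ax in moving_axes:
            phase = _shift_axis(phase, shift[ax], int(ax))
        out += phase
    out /= len(shifts_vox)
    return out


def _distance_edges(distance_range) -> np.ndarray:
    lo, hi = distance_range
    n = int(round(hi - lo))
    if n < 1 or abs(lo + n - hi) > 1e-9:
        raise ParameterError("distance range must span a whole number of 1 mm bins")
    return lo + np.arange(n + 1, dtype=float)


def cross_histogram(
    density: np.ndarray,
    distance: DistanceMap,
    lung_mask: np.ndarray,
    density_bin_hu: float = DENSITY_BIN_HU,
    density_range_hu=DENSITY_HU_RANGE,
    distance_range_mm=DENSITY_RANGE_MM,
) -> CrossHistogram:
    """2D cross-histogram of density vs signed distance over lung voxels.

    Each lung voxel whose center distance falls in the half-open range is
    counted once; densities are clipped into the histogram range so the
    total count equals the number of in-range lung voxels.
    """
    dist_edges = _distance_edges(distance_range_mm)
    lo_hu, hi_hu = density_range_hu
    n_dens = int(np.ceil((hi_hu - lo_hu) / density_bin_hu))
    dens_edges = lo_hu + density_bin_hu * np.arange(n_dens + 1, dtype=float)

    lung_mask = np.asarray(lung_mask, dtype=bool)
    d = distance.values
    sel = lung_mask & (d >= dist_edges[0]) & (d < dist_edges[-1])
    if not sel.any():
        warnings.warn("no lung voxels fall inside the distance range; histogram is empty")
        counts = np.zeros((n_dens, len(dist_edges) - 1))
        return CrossHistogram(counts, dens_edges, dist_edges)

    dens = np.clip(density[sel], lo_hu, np.nextafter(dens_edges[-1], -np.inf))
    dist_idx = np.floor(d[sel] - dist_edges[0]).astype(np.intp)
    dens_idx = np.minimum(
        ((dens - lo_hu) / density_bin_hu).astype(np.intp), n_dens - 1
    )
    flat = dens_idx * (len(dist_edges) - 1) + dist_idx
    counts = np.bincount(flat, minlength=n_dens * (len(dist_edges) - 1)).reshape(
        n_dens, len(dist_edges) - 1
    ).astype(float)
    return CrossHistogram(counts, dens_edges, dist_edges)


def weighted_percentile(values: np.ndarray, counts: np.ndarray, q: float) -> float:
    """Percentile with linear interpolation on a (value, count) histogram.

    Equivalent to ``np.percentile(np.repeat(values, counts), q)`` without
    materialising the expanded sample.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise UsageError("weighted_percentile on empty histogram")
    rank = q / 100.0 * (n - 1.0)
    lo_i, hi_i = int(np.floor(rank)), int(np.ceil(rank))
    cum = np.cumsum(counts)
    v_lo = values[np.searchsorted(cum, lo_i, side="right")]
    v_hi = values[np.searchsorted(cum, hi_i, side="right")]
    frac = rank - lo_i
    return float(v_lo + frac * (v_hi - v_lo))


def smooth_curve(values: np.ndarray, sigma_mm: float, bin_mm: float = 1.0) -> np.ndarray:
    """Gaussian smoothing along the distance axis, reflective boundaries."""
    if sigma_mm <= 0:
        return np.asarray(values, dtype=float).copy()
    return ndimage.gaussian_filter1d(
        np.asarray(values, dtype=float), sigma=sigma_mm / bin_mm, mode="reflect"
    )


def _fill_empty(values: np.ndarray, empty: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Carry values from the nearest non-empty annulus into empty annuli."""
    filled = list(np.nonzero(empty)[0])
    if not filled:
        return values, []
    good = np.nonzero(~empty)[0]
    if len(good) == 0:
        raise UsageError("all annuli are empty; no curve can be formed")
    out = values.copy()
    for i in filled:
        out[i] = values[good[np.argmin(np.abs(good - i))]]
    return out, filled


def density_curves(hist: CrossHistogram, sigma_mm: float = SMOOTH_SIGMA_MM) -> dict[str, RadialCurve]:
    """Mean, 90th percentile and SD density per annulus, smoothed.

    Statistics are computed from density bin centers weighted by counts;
    the percentile uses linear interpolation, the SD the population
    convention.  Empty annuli are filled from the nearest non-empty one
    (flagged in ``filled_bins``) before smoothing.
    """
    centers = hist.density_centers
    dist_centers = hist.distance_centers
    counts = hist.counts
    n_ann = counts.shape[1]
    totals = counts.sum(axis=0)
    empty = totals == 0

    mean = np.zeros(n_ann)
    p90 = np.zeros(n_ann)
    sd = np.zeros(n_ann)
    for j in range(n_ann):
        if empty[j]:
            continue
        w = counts[:, j]
        m = float(np.dot(w, centers) / totals[j])
        mean[j] = m
        sd[j] = float(np.sqrt(max(np.dot(w, (centers - m) ** 2) / totals[j], 0.0)))
        p90[j] = weighted_percentile(centers, w, 90.0)

    out = {}
    for name, vals in (("density_mean", mean), ("density_p90", p90), ("density_sd", sd)):
        vals, flagged = _fill_empty(vals, empty)
        out[name] = RadialCurve(
            metric=name,
            distance_mm=dist_centers.copy(),
            values=smooth_curve(vals, sigma_mm),
            sigma_mm=sigma_mm,
            filled_bins=flagged,
        )
    return out


def dose_curves(
    dose_eqd2: np.ndarray,
    distance: DistanceMap,
    body_mask: np.ndarray,
    distance_range_mm=DOSE_RANGE_MM,
    threshold_gy: float = 30.0,
    sigma_mm: float = SMOOTH_SIGMA_MM,
) -> dict[str, RadialCurve]:
    """Per-annulus dose SD, fraction below the EQD2 threshold, and mean.

    Works on the blurred EQD2 volume cropped to the body contour.  The mean
    curve is extracted for visualisation; the SD (population convention) and
    the low-dose fraction are the model-facing incidental-dose metrics.
    """
    edges = _distance_edges(distance_range_mm)
    n_ann = len(edges) - 1
    body_mask = np.asarray(body_mask, dtype=bool)
    d = distance.values
    sel = body_mask & (d >= edges[0]) & (d < edges[-1])
    if not sel.any():
        warnings.warn("no body voxels fall inside the dose distance range")
    idx = np.floor(d[sel] - edges[0]).astype(np.intp)
    vals = np.asarray(dose_eqd2, dtype=float)[sel]

    n = np.bincount(idx, minlength=n_ann).astype(float)
    s1 = np.bincount(idx, weights=vals, minlength=n_ann)
    s2 = np.bincount(idx, weights=vals * vals, minlength=n_ann)
    n_lt = np.bincount(idx, weights=(vals < threshold_gy).astype(float), minlength=n_ann)
    empty = n == 0
    safe_n = np.where(empty, 1.0, n)
    mean = s1 / safe_n
    var = np.maximum(s2 / safe_n - mean**2, 0.0)
    sd = np.sqrt(var)
    frac = n_lt / safe_n

    centers = 0.5 * (edges[:-1] + edges[1:])
    out = {}
    for name, v in (("dose_sd", sd), ("dose_frac_lt30", frac), ("dose_mean", mean)):
        v, flagged = _fill_empty(v, empty)
        out[name] = RadialCurve(
            metric=name,
            distance_mm=centers.copy(),
            values=smooth_curve(v, sigma_mm),
            sigma_mm=sigma_mm,
            filled_bins=flagged,
        )
    return out


def structure_dose_stats(dose: np.ndarray, mask: np.ndarray, structure: str = "GTV") -> DoseStatistics:
    """Mean / max / min / SD (population) of dose inside a structure mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError(f"empty {structure} mask: dose statistics undefined")
    vals = np.asarray(dose, dtype=float)[mask]
    return DoseStatistics(
        structure=structure,
        mean=float(vals.mean()),
        max=float(vals.max()),
        min=float(vals.min()),
        sd=float(vals.std()),
    )
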