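"""Radial feature primitives: distances, EQD2, blurring, curves."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from coxradius import radial
from coxradius.errors import GeometryError, ParameterError, UsageError


def digital_sphere(shape, center, radius_mm, spacing):
    idx = np.indices(shape)
    d2 = sum(((g - c) * spacing) ** 2 for g, c in zip(idx, center))
    return d2 <= radius_mm**2


def brute_force_signed_distance(mask, spacing):
    """Exhaustive nearest-opposite-voxel search (the independent oracle)."""
    spacing = np.asarray(spacing, dtype=float)
    pts = np.argwhere(np.ones_like(mask)) * spacing
    inside = mask.ravel()
    dist = np.empty(mask.size)
    inside_pts = pts[inside]
    outside_pts = pts[~inside]
    for i, (p, is_in) in enumerate(zip(pts, inside)):
        other = outside_pts if is_in else inside_pts
        d = np.sqrt(((other - p) ** 2).sum(axis=1)).min()
        dist[i] = -d if is_in else d
    half = 0.5 * spacing.min()
    signed = dist - np.sign(dist) * half
    return signed.reshape(mask.shape)


class TestSignedDistance:
    def test_sphere_center_depth(self):
        spacing = 1.0
        mask = digital_sphere((25, 25, 25), (12, 12, 12), 10.0, spacing)
        dm = radial.signed_distance(mask, (spacing,) * 3)
        assert dm.values[12, 12, 12] == pytest.approx(-10.0, abs=1.5 * spacing)

    def test_boundary_voxels_near_zero(self):
        mask = digital_sphere((21, 21, 21), (10, 10, 10), 6.0, 1.0)
        dm = radial.signed_distance(mask, (1.0,) * 3)
        # boundary voxels: in mask with an out-of-mask 6-neighbour
        from scipy.ndimage import binary_erosion

        boundary = mask & ~binary_erosion(mask)
        half_diag = 0.5 * np.sqrt(3.0)
        assert np.all(np.abs(dm.values[boundary]) <= half_diag + 1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((12, 12, 12), dtype=bool)
        # random blob: a few dilated seeds
        from scipy.ndimage import binary_dilation

        mask[tuple(rng.integers(3, 9, size=(3, 5)))] = True
        mask = binary_dilation(mask, iterations=2)
        spacing = (1.0, 1.0, 2.5) if seed else (1.0, 1.0, 1.0)
        dm = radial.signed_distance(mask, spacing)
        oracle = brute_force_signed_distance(mask, spacing)
        assert np.max(np.abs(dm.values - oracle)) < 1e-9

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(GeometryError):
            radial.signed_distance(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))
        with pytest.raises(GeometryError):
            radial.signed_distance(np.ones((4, 4, 4), dtype=bool), (1, 1, 1))


class TestEqd2:
    @pytest.mark.parametrize(
        "dose,n,expected",
        [(60.0, 5, 110.0), (50.0, 5, 250.0 / 3.0), (2.0, 1, 2.0), (0.0, 5, 0.0)],
    )
    def test_closed_form(self, dose, n, expected):
        assert radial.eqd2(np.array([dose]), n)[0] == pytest.approx(expected, rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            radial.eqd2(np.ones(3), 5, alpha_beta=0.0)
        with pytest.raises(ParameterError):
            radial.eqd2(-np.ones(3), 5)


class TestBlurDose:
    def test_zero_motion_is_identity(self, rng):
        dose = rng.random((10, 10, 10))
        traj = radial.sinusoidal_trajectory(0.0)
        assert np.array_equal(radial.blur_dose(dose, traj, (2, 2, 2)), dose)

    def test_uniform_dose_invariant(self):
        dose = np.full((8, 8, 8), 42.0)
        traj = radial.sinusoidal_trajectory(1.2)
        out = radial.blur_dose(dose, traj, (2, 2, 2))
        assert np.allclose(out, 42.0)

    def test_two_phase_step_average(self):
        # 1D step along axis 0, +/-1 voxel two-phase trajectory: the blurred
        # profile is the hand-computed average of the two shifted copies
        dose = np.zeros((6, 1, 1))
        dose[3:, 0, 0] = 10.0
        traj = np.array([[2.0, 0, 0], [-2.0, 0, 0]])  # mm at 2 mm spacing
        out = radial.blur_dose(dose, traj, (2.0, 2.0, 2.0))
        up = np.array([0, 0, 0, 10, 10, 10.0])  # sample at i+1
        down = np.array([0, 0, 0, 0, 10, 10.0])  # sample at i-1 (edge clamp)
        up = np.array([dose[min(i + 1, 5), 0, 0] for i in range(6)])
        down = np.array([dose[max(i - 1, 0), 0, 0] for i in range(6)])
        assert np.allclose(out[:, 0, 0], (up + down) / 2.0)

    def test_displacement_exceeding_grid(self):
        with pytest.raises(GeometryError):
            radial.blur_dose(np.zeros((4, 4, 4)), np.array([[100.0, 0, 0]]), (2, 2, 2))


@pytest.fixture()
def simple_geometry():
    mask = digital_sphere((24, 24, 24), (11.5, 11.5, 11.5), 6.0, 2.0)
    dm = radial.signed_distance(mask, (2.0,) * 3)
    lung = ~mask
    return mask, dm, lung


class TestCrossHistogram:
    def test_constant_lung_density(self, simple_geometry):
        mask, dm, lung = simple_geometry
        density = np.full(mask.shape, -800.0)
        hist = radial.cross_histogram(density, dm, lung)
        occupied = hist.counts.sum(axis=0) > 0
        bin_of_800 = np.digitize(-800.0, hist.density_edges) - 1
        col_mass = hist.counts[:, occupied]
        assert np.all(col_mass.sum(axis=0) == hist.counts[bin_of_800, occupied])

    def test_total_counts_match_direct_masking(self, simple_geometry, rng):
        mask, dm, lung = simple_geometry
        density = rng.normal(-700, 100, mask.shape)
        hist = radial.cross_histogram(density, dm, lung)
        expected = np.sum(lung & (dm.values >= -5.0) & (dm.values < 20.0))
        assert hist.counts.sum() == expected

    def test_fine_bins_preserve_annulus_mean(self, simple_geometry, rng):
        mask, dm, lung = simple_geometry
        density = rng.normal(-700, 60, mask.shape)
        fine = radial.cross_histogram(density, dm, lung, density_bin_hu=1.0)
        sel = lung & (dm.values >= 6) & (dm.values < 7)
        assert sel.any()
        col = np.nonzero(fine.distance_centers == 6.5)[0][0]
        w = fine.counts[:, col]
        binned_mean = np.dot(w, fine.density_centers) / w.sum()
        assert binned_mean == pytest.approx(density[sel].mean(), abs=0.5)


class TestWeightedPercentile:
    @hyp_settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=6), min_size=3, max_size=12).filter(
            lambda w: sum(w) > 0
        ),
        st.floats(min_value=0, max_value=100),
    )
    def test_matches_numpy_on_expanded_sample(self, weights, q):
        values = np.arange(len(weights), dtype=float)
        expanded = np.repeat(values, weights)
        got = radial.weighted_percentile(values, np.array(weights, dtype=float), q)
        assert got == pytest.approx(np.percentile(expanded, q), abs=1e-9)


class TestDensityCurves:
    def _hist_from_columns(self, columns, centers):
        counts = np.column_stack(columns).astype(float)
        step = centers[1] - centers[0] if len(centers) > 1 else 1.0
        density_edges = np.concatenate([centers - step / 2, [centers[-1] + step / 2]])
        distance_edges = np.arange(-5.0, -5.0 + counts.shape[1] + 1)
        return radial.CrossHistogram(counts, density_edges, distance_edges)

    def test_constant_density_fixed_point(self):
        centers = np.arange(-810.0, -790.0)
        col = np.zeros(len(centers))
        col[10] = 50  # all voxels at -800
        hist = self._hist_from_columns([col] * 6, centers)
        curves = radial.density_curves(hist)
        for name, expect in (("density_mean", -800.0), ("density_p90", -800.0), ("density_sd", 0.0)):
            assert np.allclose(curves[name].values, expect)

    def test_p90_linear_interpolation(self):
        # one annulus holding the values 1..10 HU once each -> p90 = 9.1
        centers = np.arange(1.0, 11.0)
        col = np.ones(10)
        hist = self._hist_from_columns([col], centers)
        curves = radial.density_curves(hist, sigma_mm=0.0)
        assert curves["density_p90"].values[0] == pytest.approx(9.1)

    def test_impulse_smoothing_equals_kernel(self):
        impulse = np.zeros(25)
        impulse[12] = 1.0
        smoothed = radial.smooth_curve(impulse, sigma_mm=1.5)
        from scipy.ndimage import gaussian_filter1d

        kernel = gaussian_filter1d(impulse, 1.5, mode="constant")
        # away from boundaries reflect == constant padding; weights normalized
        assert np.allclose(smoothed, kernel, atol=1e-12)
        assert smoothed.sum() == pytest.approx(1.0, abs=1e-9)

    def test_smoothing_conserves_constant_mass(self):
        const = np.full(25, 3.7)
        assert np.allclose(radial.smooth_curve(const, 1.5), const, atol=1e-9)

    def test_empty_annulus_filled_and_flagged(self):
        centers = np.array([-800.0, -700.0])
        cols = [np.array([5.0, 0.0]), np.array([0.0, 0.0]), np.array([0.0, 4.0])]
        hist = self._hist_from_columns(cols, centers)
        curves = radial.density_curves(hist, sigma_mm=0.0)
        assert curves["density_mean"].filled_bins == [1]
        assert curves["density_mean"].values[1] in (-800.0, -700.0)


class TestDoseCurves:
    def test_threshold_and_sd_two_level_annulus(self, simple_geometry):
        mask, dm, lung = simple_geometry
        # half of the annulus voxels at 20 Gy, half at 40 Gy
        sel = (dm.values >= 6.0) & (dm.values < 7.0)
        dose = np.full(mask.shape, 100.0)
        idx = np.argwhere(sel)
        dose[tuple(idx[: len(idx) // 2].T)] = 20.0
        dose[tuple(idx[len(idx) // 2 :].T)] = 40.0
        assert len(idx) % 2 == 0
        curves = radial.dose_curves(dose, dm, np.ones_like(mask), sigma_mm=0.0)
        col = np.nonzero(curves["dose_sd"].distance_mm == 6.5)[0][0]
        assert curves["dose_frac_lt30"].values[col] == pytest.approx(0.5)
        assert curves["dose_sd"].values[col] == pytest.approx(10.0)

    def test_all_above_threshold_gives_zero_fraction(self, simple_geometry):
        mask, dm, lung = simple_geometry
        curves = radial.dose_curves(np.full(mask.shape, 35.0), dm, np.ones_like(mask))
        assert np.all(curves["dose_frac_lt30"].values == 0.0)

    def test_uniform_dose_zero_sd(self, simple_geometry):
        mask, dm, _ = simple_geometry
        curves = radial.dose_curves(np.full(mask.shape, 70.0), dm, np.ones_like(mask))
        assert np.allclose(curves["dose_sd"].values, 0.0, atol=1e-9)
        assert np.allclose(curves["dose_mean"].values, 70.0)


class TestStructureDoseStats:
    def test_uniform(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        s = radial.structure_dose_stats(np.full(mask.shape, 110.0), mask)
        assert (s.mean, s.max, s.min, s.sd) == (110.0, 110.0, 110.0, 0.0)

    def test_two_voxel_population_sd(self):
        mask = np.array([True, True, False])
        dose = np.array([100.0, 120.0, 999.0])
        s = radial.structure_dose_stats(dose, mask)
        assert s.mean == pytest.approx(110.0)
        assert s.sd == pytest.approx(10.0)  # population convention

    def test_empty_mask_rejected(self):
        with pytest.raises(GeometryError):
            radial.structure_dose_stats(np.ones((2, 2)), np.zeros((2, 2), dtype=bool))


def test_annulus_partition_counts_each_voxel_once(simple_geometry, rng):
    mask, dm, lung = simple_geometry
    density = rng.normal(-700, 50, mask.shape)
    hist = radial.cross_histogram(density, dm, lung)
    in_range = lung & (dm.values >= -5) & (dm.values < 20)
    per_bin = hist.counts.sum(axis=0)
    assert per_bin.sum() == in_range.sum()
    # each voxel lands in exactly the bin containing its center distance
    d = dm.values[in_range]
    expected = np.bincount(np.floor(d + 5).astype(int), minlength=25)
    assert np.array_equal(per_bin, expected)
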