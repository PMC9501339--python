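import numpy as np
import pytest

import oracles
from biofilmorph import (
    BinaryGrid,
    SyntheticSpec,
    area_to_volume,
    biovolume,
    coverage_fraction,
    fractal_dimension_2d,
    generate_stack,
    height_map,
    mean_thickness,
    roughness_coefficient,
    spherical_cap_volume,
)
from biofilmorph.morphology3d import analyze_stack, boundary_pixels_2d


def make_mask(arr, dx=1.0, dy=1.0, dz=1.0):
    return BinaryGrid(mask=np.asarray(arr, dtype=bool), dx=dx, dy=dy, dz=dz)


class TestBiovolume:
    def test_counts_times_voxel_volume(self):
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[0, :2, :2] = True
        mask[1, :2, :2] = True  # 8 voxels
        assert biovolume(make_mask(mask, dx=0.5, dy=0.5, dz=1.0)) == pytest.approx(2.0)

    def test_empty_mask_is_zero(self):
        assert biovolume(make_mask(np.zeros((3, 4, 4)))) == 0.0

    def test_voxelized_cap_close_to_analytic(self):
        """A voxelized spherical cap (r=10 μm, h=6 μm, 0.25 μm voxels) matches
        πh²(3r−h)/3 within 3%."""
        spec = SyntheticSpec(
            seed=0, width_um=32, length_um=32, n_slices=32,
            dx=0.25, dy=0.25, dz=0.25,
            placement="center", n_colonies=1,
            radius_median_um=10.0, radius_log_sigma=0.0,
            cap_height_ratio=0.6, noise_sd=0.0,
        )
        _, truth, record = generate_stack(spec)
        analytic = spherical_cap_volume(10.0, 6.0)
        assert record["analytic_volume_um3"] == pytest.approx(analytic)
        assert biovolume(truth) == pytest.approx(analytic, rel=0.03)

    def test_equals_sum_of_slice_coverages(self, random_mask_factory):
        mask = random_mask_factory(5)
        nz, ny, nx = mask.shape
        slice_area = ny * nx * mask.dx * mask.dy
        total = sum(
            coverage_fraction(mask, z) * slice_area * mask.dz for z in range(nz)
        )
        assert biovolume(mask) == pytest.approx(total)


class TestCoverage:
    def test_full_slice(self, slab_mask):
        assert coverage_fraction(slab_mask, z=0) == 1.0

    def test_half_plane(self):
        mask = np.zeros((1, 8, 8), dtype=bool)
        mask[0, :4, :] = True
        assert coverage_fraction(make_mask(mask), z=0) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_per_slice_matches_pixel_count_oracle(self, seed, random_mask_factory):
        mask = random_mask_factory(seed, shape=(6, 12, 12))
        for z in range(6):
            assert coverage_fraction(mask, z) == oracles.naive_slice_coverage(mask.mask, z)

    def test_substratum_coverage_matches_oracle(self, random_mask_factory):
        mask = random_mask_factory(3, p=0.05)
        assert coverage_fraction(mask) == oracles.naive_substratum_coverage(mask.mask)

    def test_out_of_range_slice(self, slab_mask):
        with pytest.raises(IndexError):
            coverage_fraction(slab_mask, z=10)


class TestAreaToVolume:
    def test_single_voxel_is_its_own_boundary(self):
        mask = np.zeros((3, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        assert area_to_volume(make_mask(mask)) == pytest.approx(1.0)

    def test_solid_cube_488_boundary_voxels(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        assert area_to_volume(make_mask(mask)) == pytest.approx(0.488)

    def test_thicker_slab_has_lower_ratio(self):
        thin = np.ones((2, 8, 8), dtype=bool)
        thick = np.ones((4, 8, 8), dtype=bool)
        assert area_to_volume(make_mask(thick)) < area_to_volume(make_mask(thin))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_neighbor_scan_oracle(self, seed, random_mask_factory):
        mask = random_mask_factory(seed, shape=(8, 10, 10))
        n_surface = oracles.naive_surface_voxels(mask.mask)
        expected = n_surface * mask.dx * mask.dy / (
            np.count_nonzero(mask.mask) * mask.dx * mask.dy * mask.dz
        )
        assert area_to_volume(mask) == pytest.approx(expected)

    def test_empty_mask_undefined(self):
        with pytest.raises(ValueError):
            area_to_volume(make_mask(np.zeros((2, 4, 4))))


class TestHeightMapAndThickness:
    def test_uniform_slab(self, slab_mask):
        hm = height_map(slab_mask)
        assert np.all(hm.h == 10.0)
        assert mean_thickness(hm) == 10.0

    def test_empty_mask_all_zero(self):
        hm = height_map(make_mask(np.zeros((5, 4, 4))))
        assert np.all(hm.h == 0.0)
        assert not hm.covered.any()

    def test_internal_voids_ignored(self):
        mask = np.ones((6, 4, 4), dtype=bool)
        mask[2:4] = False  # void in the middle; top surface unchanged
        hm = height_map(make_mask(mask))
        assert np.all(hm.h == 6.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_argmax_oracle(self, seed, random_mask_factory):
        mask = random_mask_factory(seed, dz=1.7)
        np.testing.assert_allclose(
            height_map(mask).h, oracles.naive_height_map(mask.mask, 1.7)
        )

    def test_net_volume_variant_counts_all_voxels(self):
        mask = np.ones((6, 4, 4), dtype=bool)
        mask[2:4] = False
        hm = height_map(make_mask(mask), net_volume=True)
        assert np.all(hm.h == 4.0)

    def test_half_covered_field_means(self):
        mask = np.zeros((10, 4, 4), dtype=bool)
        mask[:, :2, :] = True
        hm = height_map(make_mask(mask))
        assert mean_thickness(hm) == pytest.approx(5.0)
        assert mean_thickness(hm, covered_only=True) == pytest.approx(10.0)

    def test_covered_only_never_smaller(self, random_mask_factory):
        for seed in range(10):
            mask = random_mask_factory(seed, p=0.02)
            hm = height_map(mask)
            if hm.covered.any():
                assert mean_thickness(hm, covered_only=True) >= mean_thickness(hm)


class TestRoughnessCoefficient:
    def test_flat_slab_zero(self, slab_mask):
        assert roughness_coefficient(height_map(slab_mask)) == 0.0

    def test_two_point_distribution(self):
        # half the columns at h, half at 3h: mean 2h, SD h, eta = 0.5
        mask = np.zeros((6, 4, 4), dtype=bool)
        mask[:2, :2, :] = True
        mask[:6, 2:, :] = True
        assert roughness_coefficient(height_map(make_mask(mask))) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sd_over_mean_oracle(self, seed, random_mask_factory):
        mask = random_mask_factory(seed)
        hm = height_map(mask)
        h = hm.h.ravel()
        expected = np.sqrt(np.mean((h - h.mean()) ** 2)) / h.mean()
        assert roughness_coefficient(hm) == pytest.approx(expected)

    def test_empty_map_undefined(self):
        with pytest.raises(ValueError):
            roughness_coefficient(height_map(make_mask(np.zeros((2, 4, 4)))))


class TestFractalDimension:
    def test_straight_boundary_near_one(self):
        slice_ = np.zeros((256, 256), dtype=bool)
        slice_[80:180, 80:180] = True
        d = fractal_dimension_2d(slice_)
        assert d == pytest.approx(1.0, abs=0.1)

    def test_matches_box_counting_oracle(self):
        rng = np.random.default_rng(2)
        slice_ = np.zeros((64, 64), dtype=bool)
        for _ in range(12):
            cy, cx = rng.integers(8, 56, size=2)
            r = rng.integers(3, 8)
            yy, xx = np.ogrid[:64, :64]
            slice_ |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        raw = fractal_dimension_2d(slice_, clamp=False)
        oracle = oracles.naive_box_count_dimension(boundary_pixels_2d(slice_))
        assert raw == pytest.approx(oracle, abs=1e-9)

    def test_reported_value_in_unit_band(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            slice_ = rng.random((64, 64)) < 0.4
            if slice_.any() and not slice_.all():
                assert 1.0 <= fractal_dimension_2d(slice_) <= 2.0

    def test_scale_consistency_under_upscaling(self):
        rng = np.random.default_rng(9)
        slice_ = np.zeros((64, 64), dtype=bool)
        yy, xx = np.ogrid[:64, :64]
        for _ in range(6):
            cy, cx = rng.integers(12, 52, size=2)
            slice_ |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 49
        up = np.kron(slice_, np.ones((2, 2), dtype=bool))
        d0 = fractal_dimension_2d(slice_)
        d2 = fractal_dimension_2d(up)
        assert abs(d0 - d2) <= 0.1

    @pytest.mark.parametrize("fill", [0, 1])
    def test_empty_or_full_slice_undefined(self, fill):
        with pytest.raises(ValueError):
            fractal_dimension_2d(np.full((32, 32), bool(fill)))


class TestInvariants:
    def test_metrics_invariant_under_xy_transpose(self, random_mask_factory):
        mask = random_mask_factory(11, dx=0.5, dy=0.5)
        swapped = BinaryGrid(
            mask=mask.mask.transpose(0, 2, 1), dx=mask.dy, dy=mask.dx, dz=mask.dz
        )
        assert biovolume(mask) == biovolume(swapped)
        assert coverage_fraction(mask) == coverage_fraction(swapped)
        assert area_to_volume(mask) == pytest.approx(area_to_volume(swapped))
        assert mean_thickness(height_map(mask)) == pytest.approx(
            mean_thickness(height_map(swapped))
        )
        assert roughness_coefficient(height_map(mask)) == pytest.approx(
            roughness_coefficient(height_map(swapped))
        )

    def test_biovolume_resolution_convergence(self):
        """Voxelized volume approaches the analytic cap volume as voxels shrink."""
        errors = []
        for voxel in (1.0, 0.5, 0.25):
            spec = SyntheticSpec(
                seed=0, width_um=32, length_um=32,
                n_slices=int(12 / voxel), dx=voxel, dy=voxel, dz=voxel,
                placement="center", n_colonies=1,
            radius_median_um=10.0, radius_log_sigma=0.0,
                cap_height_ratio=0.6, noise_sd=0.0,
            )
            _, truth, record = generate_stack(spec)
            analytic = record["analytic_volume_um3"]
            errors.append(abs(biovolume(truth) - analytic) / analytic)
        assert errors[2] < errors[0]
        assert errors[2] < 0.03


class TestAnalyzeStack:
    def test_report_has_fixed_schema(self):
        spec = SyntheticSpec(seed=1, noise_sd=0.0)
        _, truth, _ = generate_stack(spec)
        report = analyze_stack(truth, rng_seed=0).to_dict()
        assert set(report) == {
            "biovolume_um3", "coverage_pct", "area_to_volume_per_um",
            "mean_thickness_um", "roughness_coefficient", "fractal_dimension",
            "hopkins_index", "aggregation_coefficient",
        }
        assert report["biovolume_um3"] > 0
        assert 0 <= report["coverage_pct"] <= 100
        assert 0 <= report["aggregation_coefficient"] <= 1
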