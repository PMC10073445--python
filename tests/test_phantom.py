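"""Phantom simulator: rasterization accuracy, PSF blur, Poisson noise."""

import math

import numpy as np
import pytest

from qspect.phantom import (
    ActivityVolume,
    Cylinder,
    GridSpec,
    PhantomSpec,
    Sphere,
    add_poisson_noise,
    apply_system_blur,
    generate_phantom_series,
    rasterize_phantom,
    sphere_for_volume,
)


def count_inside(vol, model, spec):
    hot = model.predict_counts(spec.concentration) * vol.grid.voxel_volume_mL
    return int(np.count_nonzero(np.isclose(vol.values, hot)))


class TestRasterize:
    def test_unit_sphere_voxel_count(self, fine_grid, ref_model):
        # sphere of analytic volume 1.000 mL at 1 mm spacing -> ~1000 inside voxels
        spec = PhantomSpec(geometry=Sphere((32.0, 32.0, 32.0), 6.2035), concentration=1.0)
        assert abs(spec.true_volume_mL - 1.0) < 1e-3
        vol = rasterize_phantom(spec, fine_grid, ref_model)
        inside = count_inside(vol, ref_model, spec)
        assert abs(inside - 1000) / 1000 < 0.04

    def test_equal_contrast_gives_constant_volume(self, small_grid, ref_model):
        spec = PhantomSpec(geometry=Sphere((32.0, 32.0, 32.0), 10.0),
                           concentration=2.0, background_concentration=2.0)
        vol = rasterize_phantom(spec, small_grid, ref_model)
        assert np.ptp(vol.values) == 0.0

    def test_cylinder_volume_matches_brute_force_oracle(self, ref_model):
        # r=50 mm, h=127.3 mm -> analytic pi r^2 h = 999.9 mL
        grid = GridSpec((80, 60, 60), (2.0, 2.0, 2.0))
        cyl = Cylinder(center_mm=(80.0, 60.0, 60.0), radius_mm=50.0, height_mm=127.3)
        assert abs(cyl.volume_mL - 1000.0) < 1.0
        spec = PhantomSpec(geometry=cyl, concentration=1.0)
        vol = rasterize_phantom(spec, grid, ref_model)
        inside = count_inside(vol, ref_model, spec)
        # independent brute-force voxel-center scan
        oracle = 0
        for iz in range(grid.shape[0]):
            z = (iz + 0.5) * 2.0
            if abs(z - 80.0) > 127.3 / 2:
                continue
            for iy in range(grid.shape[1]):
                y = (iy + 0.5) * 2.0
                for ix in range(grid.shape[2]):
                    x = (ix + 0.5) * 2.0
                    if math.hypot(y - 60.0, x - 60.0) <= 50.0:
                        oracle += 1
        assert inside == oracle
        assert abs(inside * grid.voxel_volume_mL - 1000.0) / 1000.0 < 0.02

    def test_geometry_exceeding_grid_names_axis(self, small_grid, ref_model):
        spec = PhantomSpec(geometry=Sphere((32.0, 32.0, 60.0), 10.0), concentration=1.0)
        with pytest.raises(ValueError, match="axis x"):
            rasterize_phantom(spec, small_grid, ref_model)

    def test_monotone_contrast(self, small_grid, ref_model):
        geom = Sphere((32.0, 32.0, 32.0), 12.0)
        lo = rasterize_phantom(PhantomSpec(geom, concentration=1.0), small_grid, ref_model)
        hi = rasterize_phantom(PhantomSpec(geom, concentration=2.0), small_grid, ref_model)
        assert np.all(hi.values >= lo.values)

    def test_voxelization_error_shrinks_with_spacing(self, ref_model):
        geom = Sphere((32.0, 32.0, 32.0), 12.0)
        errs = []
        for spacing, n in ((2.0, 32), (1.0, 64)):
            grid = GridSpec((n, n, n), (spacing,) * 3)
            spec = PhantomSpec(geom, concentration=1.0)
            vol = rasterize_phantom(spec, grid, ref_model)
            est = count_inside(vol, ref_model, spec) * grid.voxel_volume_mL
            errs.append(abs(est - geom.volume_mL))
        assert errs[1] < errs[0]

    def test_inconsistent_true_volume_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            PhantomSpec(geometry=Sphere((0, 0, 0), 10.0), concentration=1.0,
                        true_volume_mL=5.0)


class TestBlur:
    def test_zero_fwhm_is_identity(self, small_grid, ref_model):
        spec = PhantomSpec(Sphere((32.0, 32.0, 32.0), 10.0), concentration=1.0)
        vol = rasterize_phantom(spec, small_grid, ref_model)
        out = apply_system_blur(vol, 0.0)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_uniform_volume_unchanged(self, small_grid):
        vol = ActivityVolume(small_grid, np.full(small_grid.shape, 100.0))
        out = apply_system_blur(vol, 10.0)
        np.testing.assert_allclose(out.values, 100.0, rtol=1e-9)

    def test_point_source_profile_matches_gaussian(self):
        # fwhm 10 mm at 1 mm spacing -> sigma = 4.2466 voxels; the discrete
        # kernel samples exp(-d^2 / 2 sigma^2) so profile ratios match it
        grid = GridSpec((65, 65, 65), (1.0, 1.0, 1.0))
        values = np.zeros(grid.shape)
        values[32, 32, 32] = 1.0e6
        out = apply_system_blur(ActivityVolume(grid, values), 10.0)
        sigma = 10.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        assert abs(sigma - 4.2466) < 1e-4
        center = out.values[32, 32, 32]
        for d in (1, 3, 6, 10):
            ratio = out.values[32, 32, 32 + d] / center
            assert ratio == pytest.approx(math.exp(-d**2 / (2 * sigma**2)), rel=1e-6)

    def test_counts_conserved(self, small_grid, ref_model):
        spec = PhantomSpec(Sphere((32.0, 32.0, 32.0), 14.0), concentration=2.0)
        vol = rasterize_phantom(spec, small_grid, ref_model)
        out = apply_system_blur(vol, 12.0)
        assert abs(out.total_counts - vol.total_counts) / vol.total_counts < 1e-3

    def test_negative_fwhm_rejected(self, small_grid):
        vol = ActivityVolume(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(ValueError):
            apply_system_blur(vol, -1.0)


class TestNoise:
    def test_zero_means_stay_zero(self, small_grid):
        vol = ActivityVolume(small_grid, np.zeros(small_grid.shape))
        out = add_poisson_noise(vol, seed=3)
        assert out.values.sum() == 0.0

    def test_same_seed_reproduces(self, small_grid):
        vol = ActivityVolume(small_grid, np.full(small_grid.shape, 50.0))
        a = add_poisson_noise(vol, seed=11)
        b = add_poisson_noise(vol, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_sample_mean_near_poisson_mean(self):
        grid = GridSpec((10, 100, 10), (1.0, 1.0, 1.0))
        vol = ActivityVolume(grid, np.full(grid.shape, 10_000.0))
        out = add_poisson_noise(vol, seed=7)
        assert abs(out.values.mean() - 10_000.0) / 10_000.0 < 0.01


class TestSeries:
    def test_cardinality_with_single_concentration(self, small_grid):
        series = generate_phantom_series([1.0, 2.0, 4.0], [2.0], grid=small_grid,
                                         fwhm_mm=4.0, noise=False, seed=0)
        assert len(series) == 3
        assert [round(s.true_volume_mL, 6) for s, _ in series] == [1.0, 2.0, 4.0]

    def test_fixed_seed_byte_identical(self, small_grid):
        a = generate_phantom_series([2.0, 4.0], [2.0], grid=small_grid, fwhm_mm=4.0,
                                    noise=True, seed=42)
        b = generate_phantom_series([2.0, 4.0], [2.0], grid=small_grid, fwhm_mm=4.0,
                                    noise=True, seed=42)
        for (_, va), (_, vb) in zip(a, b):
            assert va.values.tobytes() == vb.values.tobytes()

    def test_empty_lists_rejected(self, small_grid):
        with pytest.raises(ValueError):
            generate_phantom_series([], [1.0], grid=small_grid)
        with pytest.raises(ValueError):
            generate_phantom_series([6.0], [], grid=small_grid)

    def test_default_range_presets(self):
        from qspect.phantom import DEFAULT_VOLUME_RANGES
        assert DEFAULT_VOLUME_RANGES == ((6.0, 30.0), (500.0, 1500.0), (2400.0, 3200.0))
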