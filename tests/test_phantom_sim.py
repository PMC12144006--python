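import math

import numpy as np
import pytest

from petvrt import (
    ImageVolume,
    NoiseSpec,
    PhantomSpec,
    PsfSpec,
    SphereSpec,
    add_noise,
    apply_psf,
    generate_autoradiography_field,
    rasterize_phantom,
    simulate_sbr_series,
    single_sphere_phantom,
)


def total_mass(img):
    return float(img.values.sum()) * img.voxel_volume


class TestRasterize:
    def test_wallless_sphere_mass_matches_analytic_volume(self):
        spec = single_sphere_phantom(10.0, sphere_activity=1.0, background_activity=0.0)
        img = rasterize_phantom(spec, oversample=4)
        expected = math.pi / 6 * 10**3  # 523.6 mm^3
        assert total_mass(img) == pytest.approx(expected, rel=5e-3)

    def test_wall_shell_mass_matches_analytic_shell_volume(self):
        base = single_sphere_phantom(10.0)
        shell = SphereSpec("shell", base.spheres[0].center, 10.0, wall_thickness=1.0,
                           sphere_activity=0.0, wall_activity=1.0)
        spec = PhantomSpec((shell,), 0.0, base.grid_shape, base.voxel_spacing)
        img = rasterize_phantom(spec, oversample=4)
        expected = 4 * math.pi / 3 * (6**3 - 5**3)  # 381.2 mm^3
        assert total_mass(img) == pytest.approx(expected, rel=1e-2)

    def test_no_spheres_gives_uniform_background(self):
        spec = PhantomSpec((), 2.5, (8, 8, 8), (1.0, 1.0, 2.0))
        img = rasterize_phantom(spec, oversample=2)
        assert np.all(img.values == 2.5)

    def test_total_mass_matches_analytic_for_walled_sphere_in_background(self):
        # B*V_bg + A*V_sphere + W*V_wall, all displacing background
        spec = single_sphere_phantom(17.0, sphere_activity=10.0, background_activity=1.0,
                                     wall_thickness=1.0, wall_activity=0.5)
        img = rasterize_phantom(spec, oversample=4)
        s = spec.spheres[0]
        v_in = math.pi / 6 * 17**3
        v_wall = 4 * math.pi / 3 * (s.outer_radius**3 - s.inner_radius**3)
        v_grid = np.prod(spec.grid_shape) * img.voxel_volume
        expected = 10.0 * v_in + 0.5 * v_wall + 1.0 * (v_grid - v_in - v_wall)
        assert total_mass(img) == pytest.approx(expected, rel=5e-3)

    def test_overlapping_spheres_rejected(self):
        a = SphereSpec("a", (20, 20, 20), 10.0)
        b = SphereSpec("b", (25, 20, 20), 10.0)
        spec = PhantomSpec((a, b), 0.0, (40, 40, 40), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="overlap"):
            rasterize_phantom(spec)

    def test_sphere_outside_grid_rejected(self):
        s = SphereSpec("edge", (2.0, 20.0, 20.0), 10.0)
        spec = PhantomSpec((s,), 0.0, (40, 40, 40), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="outside"):
            rasterize_phantom(spec)

    def test_oversample_refinement_converges(self):
        spec = single_sphere_phantom(13.0, sphere_activity=5.0, background_activity=1.0)
        v1 = rasterize_phantom(spec, oversample=1).values
        v2 = rasterize_phantom(spec, oversample=2).values
        v4 = rasterize_phantom(spec, oversample=4).values
        d12 = np.abs(v2 - v1).max()
        d24 = np.abs(v4 - v2).max()
        assert d24 < d12


class TestPsf:
    def test_uniform_image_unchanged(self):
        img = ImageVolume(np.full((20, 20, 10), 3.0), (1.0, 1.0, 2.0))
        out = apply_psf(img, PsfSpec(7.0), background=3.0)
        assert np.allclose(out.values, 3.0)

    def test_mass_conserved_for_interior_object(self):
        spec = single_sphere_phantom(13.0, sphere_activity=1.0, background_activity=0.0)
        img = rasterize_phantom(spec, oversample=2)
        out = apply_psf(img, PsfSpec(7.0), background=0.0)
        assert total_mass(out) == pytest.approx(total_mass(img), rel=1e-3)

    def test_halfspace_step_is_halved_at_the_plane(self):
        values = np.zeros((60, 20, 20))
        values[:30] = 8.0  # step across the plane between voxels 29 and 30
        img = ImageVolume(values, (1.0, 1.0, 1.0))
        out = apply_psf(img, PsfSpec(6.0), background=0.0)
        at_plane = 0.5 * (out.values[29, 10, 10] + out.values[30, 10, 10])
        assert at_plane == pytest.approx(4.0, rel=1e-2)

    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        img = ImageVolume(rng.random((10, 10, 10)), (1.0, 1.0, 1.0))
        out = apply_psf(img, PsfSpec(0.0))
        assert np.array_equal(out.values, img.values)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = ImageVolume(rng.random((16, 16, 8)), (1.0, 1.0, 2.0))
        y = ImageVolume(rng.random((16, 16, 8)), (1.0, 1.0, 2.0))
        psf = PsfSpec(5.0)
        combo = ImageVolume(2.0 * x.values + 3.0 * y.values, x.voxel_spacing)
        lhs = apply_psf(combo, psf).values
        rhs = 2.0 * apply_psf(x, psf).values + 3.0 * apply_psf(y, psf).values
        assert np.allclose(lhs, rhs, rtol=1e-10, atol=1e-10)

    def test_gaussian_semigroup(self):
        spec = single_sphere_phantom(17.0, sphere_activity=1.0, background_activity=0.0)
        img = rasterize_phantom(spec, oversample=2)
        f1, f2 = 4.0, 5.0
        two_pass = apply_psf(apply_psf(img, PsfSpec(f1)), PsfSpec(f2))
        one_pass = apply_psf(img, PsfSpec(math.hypot(f1, f2)))
        assert np.allclose(two_pass.values, one_pass.values, atol=1e-2 * img.values.max())

    def test_singleton_axis_not_blurred(self):
        # a 2D field must keep its total contrast; the thin axis has no extent
        rng = np.random.default_rng(2)
        img = ImageVolume(rng.random((50, 50, 1)) + 1.0, (0.5, 0.5, 1.0))
        out = apply_psf(img, PsfSpec(2.0), background=float(img.values.mean()))
        assert out.values.std() > 0.1 * img.values.std()


class TestNoise:
    def test_zero_sigma_is_identity(self):
        img = ImageVolume(np.full((5, 5, 5), 7.0), (1.0, 1.0, 1.0))
        out = add_noise(img, NoiseSpec(0.0, 3))
        assert np.array_equal(out.values, img.values)

    def test_same_seed_is_bit_identical(self):
        img = ImageVolume(np.full((10, 10, 10), 2.0), (1.0, 1.0, 1.0))
        a = add_noise(img, NoiseSpec(0.1, 42))
        b = add_noise(img, NoiseSpec(0.1, 42))
        assert np.array_equal(a.values, b.values)
        c = add_noise(img, NoiseSpec(0.1, 43))
        assert not np.array_equal(a.values, c.values)

    def test_noise_std_scales_with_mean(self):
        img = ImageVolume(np.full((100, 100, 100), 10.0), (1.0, 1.0, 1.0))
        out = add_noise(img, NoiseSpec(0.05, 7))
        assert (out.values - 10.0).std() == pytest.approx(0.5, rel=1e-2)


class TestSbrSeries:
    def test_background_follows_a_over_sbr(self):
        spec = single_sphere_phantom(13.0, sphere_activity=10.0)
        series = simulate_sbr_series(spec, [2, 4, 6, 8, 10], PsfSpec(0.0))
        backgrounds = [s.background_activity for _, s in series]
        assert backgrounds == pytest.approx([5.0, 2.5, 10 / 6, 1.25, 1.0])

    def test_sbr_at_or_below_one_rejected(self):
        spec = single_sphere_phantom(13.0)
        with pytest.raises(ValueError, match="exceed"):
            simulate_sbr_series(spec, [1.0], PsfSpec(7.0))

    def test_noise_seeds_differ_between_series_members(self):
        spec = single_sphere_phantom(13.0, sphere_activity=10.0)
        series = simulate_sbr_series(spec, [5.0, 5.0], PsfSpec(0.0), NoiseSpec(0.1, 1))
        assert not np.array_equal(series[0][0].values, series[1][0].values)


class TestAutoradiography:
    def test_flat_when_no_hotspots_and_no_noise(self):
        f = generate_autoradiography_field((10, 5), 0.1, baseline=3.0,
                                           hotspot_density=0.0, pixel_noise_sigma=0.0, seed=0)
        assert f.shape == (100, 50, 1)
        assert np.all(f.values == 3.0)

    def test_deterministic_given_seed(self):
        a = generate_autoradiography_field((10, 5), 0.05, seed=9)
        b = generate_autoradiography_field((10, 5), 0.05, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_nonpositive_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            generate_autoradiography_field((0.0, 5.0), 0.1)

    def test_default_field_has_expected_resolution_and_structure(self):
        f = generate_autoradiography_field(seed=4)
        assert f.shape == (2400, 800, 1)
        assert f.voxel_spacing[0] == pytest.approx(0.025)
        cv = f.values.std(ddof=1) / f.values.mean()
        assert 0.08 < cv < 0.16  # hotspots + pixel noise, CV near 12 %
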