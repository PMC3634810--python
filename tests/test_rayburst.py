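import numpy as np
import pytest

import somafinder as sf
from somafinder.rayburst import FLAG_REFINED, FLAG_HULL, SomaSurface
from conftest import digitized_ball

VOX_DIAG = float(np.linalg.norm((0.35, 0.35, 1.0)))


class TestRayDirections:
    @pytest.mark.parametrize("level,count", [(0, 12), (1, 42), (2, 162), (3, 642)])
    def test_subdivision_counts(self, level, count):
        fan = sf.ray_directions(level)
        assert fan.n_rays == count == 10 * 4 ** level + 2
        # Euler: subdividing multiplies faces by 4
        assert len(fan.faces) == 20 * 4 ** level

    def test_unit_distinct_balanced(self, fan162):
        d = fan162.directions
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-9)
        assert len(np.unique(np.round(d, 9), axis=0)) == len(d)
        assert np.linalg.norm(d.mean(axis=0)) < 1e-9


class TestCastToHull:
    def test_ball_radius_recovered_within_voxel_diagonal(self, fan162):
        mask, center = digitized_ball(10.0)
        surf = sf.cast_to_hull(mask, center, fan162, (0.35, 0.35, 1.0))
        assert np.all(surf.radii_um >= 10.0 - VOX_DIAG)
        assert np.all(surf.radii_um <= 10.0 + VOX_DIAG)

    def test_anisotropy_handled_physically(self, fan162):
        """The same physical ball passes at two different voxel spacings."""
        mask, center = digitized_ball(8.0, spacing=(0.7, 0.7, 1.4))
        surf = sf.cast_to_hull(mask, center, fan162, (0.7, 0.7, 1.4))
        diag = float(np.linalg.norm((0.7, 0.7, 1.4)))
        assert np.all(np.abs(surf.radii_um - 8.0) <= diag)

    def test_single_voxel_mask(self, fan162):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        origin = np.array([2, 2, 2]) * np.array([0.35, 0.35, 1.0])
        surf = sf.cast_to_hull(mask, origin, fan162, (0.35, 0.35, 1.0))
        assert np.all(surf.radii_um <= VOX_DIAG)

    def test_origin_outside_mask_raises(self, fan162):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="background"):
            sf.cast_to_hull(mask, (2.0, 2.0, 2.0), fan162, (1, 1, 1))


class TestGradientField:
    def test_constant_stack_zero(self):
        g = sf.gradient_field(sf.ImageStack(np.full((5, 5, 5), 4.0)))
        assert np.allclose(g.magnitude, 0.0)

    def test_ramp_matches_sobel_arithmetic(self):
        x = np.arange(9, dtype=float)
        stack = sf.ImageStack(np.broadcast_to(x[:, None, None], (9, 9, 9)).copy(),
                              spacing=(1, 1, 1))
        g = sf.gradient_field(stack)
        assert np.isclose(g.g_xy[4, 4, 4], 8.0)
        assert np.isclose(g.g_xz[4, 4, 4], 8.0)
        assert np.isclose(g.g_yz[4, 4, 4], 0.0)
        assert np.isclose(g.magnitude[4, 4, 4], 8 * np.sqrt(2))

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 6, 6)) * 10
        g1 = sf.gradient_field(sf.ImageStack(a))
        g2 = sf.gradient_field(sf.ImageStack(a + 5.0))
        assert np.allclose(g1.magnitude, g2.magnitude)


class TestRefineSurface:
    def test_solid_ball_inside_larger_hull(self, fan162):
        """Rays pull back from an 11 um hull to the 9 um intensity edge."""
        sp = (0.35, 0.35, 1.0)
        ball9, center = digitized_ball(9.0, margin_um=4.0)
        stack = sf.ImageStack(np.where(ball9, 200.0, 30.0), spacing=sp)
        hull = SomaSurface(origin_um=np.asarray(center),
                           points_um=center + 11.0 * fan162.directions,
                           radii_um=np.full(162, 11.0),
                           flags=np.full(162, FLAG_HULL),
                           directions=fan162.directions)
        grad = sf.gradient_field(stack)
        ref = sf.refine_surface(hull, grad, fan162, 3.5)
        assert np.all(np.abs(ref.radii_um - 9.0) <= VOX_DIAG)
        assert np.all(ref.flags == FLAG_REFINED)

    def test_hollow_sphere_refines_to_outer_wall(self, fan162):
        """The cavity never captures a ray, even when the reverse-search
        window reaches the inner wall."""
        hs = sf.hollow_sphere_stack(10.0, 2.0)
        ball11, center = digitized_ball(11.0, margin_um=4.0)
        assert ball11.shape == hs.shape
        hull = sf.cast_to_hull(ball11, center, fan162, hs.spacing)
        ref = sf.refine_surface(hull, sf.gradient_field(hs), fan162, 3.5)
        assert np.all(np.abs(ref.radii_um - 10.0) <= VOX_DIAG)

    def test_classical_intensity_rayburst_stops_in_cavity(self, fan162):
        """The reference intensity-threshold variant terminates inside the
        cavity: the two implementations must disagree on this fixture."""
        hs = sf.hollow_sphere_stack(10.0, 2.0)
        center = (np.asarray(hs.shape) // 2) * np.asarray(hs.spacing)
        classical = sf.cast_intensity(hs, center, fan162, threshold=115.0)
        assert np.all(classical.radii_um < 8.0)  # stuck at/inside the inner wall

    def test_flat_gradient_keeps_hull(self, fan162):
        flat = sf.ImageStack(np.full((31, 31, 15), 50.0))
        mask, center = digitized_ball(3.0, margin_um=2.0)
        stack = sf.ImageStack(np.full(mask.shape, 50.0))
        hull = sf.cast_to_hull(mask, center, fan162, (0.35, 0.35, 1.0))
        ref = sf.refine_surface(hull, sf.gradient_field(stack), fan162, 2.0)
        assert np.array_equal(ref.radii_um, hull.radii_um)
        assert np.array_equal(ref.flags, hull.flags)

    def test_refined_radius_never_exceeds_hull(self, fan162):
        rng = np.random.default_rng(1)
        mask, center = digitized_ball(5.0, margin_um=2.15)
        data = rng.random(mask.shape) * 100
        stack = sf.ImageStack(data, spacing=(0.35, 0.35, 1.0))
        hull = sf.cast_to_hull(mask, center, fan162, stack.spacing)
        ref = sf.refine_surface(hull, sf.gradient_field(stack), fan162, 3.5)
        assert np.all(ref.radii_um <= hull.radii_um + 0.175 + 1e-9)


class TestSurfaceToVolume:
    def _sphere_surface(self, fan, r):
        origin = np.array([14.0, 14.0, 14.0])
        return SomaSurface(origin_um=origin,
                           points_um=origin + r * fan.directions,
                           radii_um=np.full(fan.n_rays, float(r)),
                           flags=np.zeros(fan.n_rays, int),
                           directions=fan.directions)

    def test_sphere_volume_within_5_percent(self, fan162):
        surf = self._sphere_surface(fan162, 10.0)
        shape = (80, 80, 28)
        vol = sf.surface_to_volume(surf, surf.origin_um, shape, (0.35, 0.35, 1.0))
        v = vol.sum() * 0.35 * 0.35 * 1.0
        assert abs(v - 4 / 3 * np.pi * 1000) / (4 / 3 * np.pi * 1000) < 0.05

    def test_scaling_radii_gives_superset(self, fan162):
        s1 = self._sphere_surface(fan162, 8.0)
        s2 = self._sphere_surface(fan162, 8.0 * 1.2)
        shape = (80, 80, 28)
        v1 = sf.surface_to_volume(s1, s1.origin_um, shape, (0.35, 0.35, 1.0))
        v2 = sf.surface_to_volume(s2, s2.origin_um, shape, (0.35, 0.35, 1.0))
        assert np.all(v2[v1])

    def test_contains_origin_and_connected(self, fan162):
        import scipy.ndimage as ndi
        rng = np.random.default_rng(2)
        origin = np.array([10.0, 10.0, 10.0])
        radii = rng.uniform(3.0, 8.0, fan162.n_rays)
        surf = SomaSurface(origin_um=origin,
                           points_um=origin + radii[:, None] * fan162.directions,
                           radii_um=radii, flags=np.zeros(fan162.n_rays, int),
                           directions=fan162.directions)
        vol = sf.surface_to_volume(surf, origin, (58, 58, 21), (0.35, 0.35, 1.0))
        o = tuple(np.round(origin / np.array([0.35, 0.35, 1.0])).astype(int))
        assert vol[o]
        _, n = ndi.label(vol, np.ones((3, 3, 3)))
        assert n == 1


class TestDetectSurface:
    def _run(self, spec_kwargs, params):
        spec = sf.PhantomSpec(shape_um=(62, 62, 62), n_somas=1, n_neurites=0,
                              noise_sigma=0, placement="uniform",
                              min_separation_um=1, ellipticity=0.0, **spec_kwargs)
        stack, truth = sf.generate_phantom(spec)
        records = sf.locate_somas(stack, params)
        assert len(records) == 1
        sf.detect_surface(records[0], stack, params)
        t = truth.somas[0]
        ov = sf.masks_overlap(records[0].volume_mask, records[0].volume_lo_vox,
                              t.mask, t.mask_lo_vox)
        return records[0], t, ov

    def test_solid_soma_overlap(self, params):
        _, _, ov = self._run(dict(soma_diam_range=(21, 21), hollow_fraction=0.0,
                                  seed=21), params)
        assert ov >= 0.85

    def test_hollowness_robustness(self, params):
        """Hollow and solid somas of the same size recover equally well."""
        _, _, ov_solid = self._run(dict(soma_diam_range=(21, 21),
                                        hollow_fraction=0.0, seed=21), params)
        _, _, ov_hollow = self._run(dict(soma_diam_range=(21, 21),
                                         hollow_fraction=1.0, seed=21), params)
        assert abs(ov_solid - ov_hollow) <= 0.05

    def test_attached_neurite_does_not_drag_surface(self, params):
        """No surface point may leak along an attached tube beyond 1.5 um
        outside the true soma sphere (the hull constraint suppresses it)."""
        spec = sf.PhantomSpec(shape_um=(62, 62, 62), n_somas=1, n_neurites=1,
                              soma_diam_range=(21, 21), hollow_fraction=0.0,
                              noise_sigma=0, placement="uniform",
                              min_separation_um=1, ellipticity=0.0, seed=31)
        stack, truth = sf.generate_phantom(spec)
        records = sf.locate_somas(stack, params)
        assert len(records) == 1
        sf.detect_surface(records[0], stack, params)
        t = truth.somas[0]
        d = np.linalg.norm(records[0].surface_points - np.asarray(t.centroid_um),
                           axis=1)
        assert np.all(d <= t.diameter_um / 2 + 1.5)
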