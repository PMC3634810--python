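import numpy as np
import pytest
import scipy.ndimage as ndi

import somafinder as sf
from somafinder.localize import (ellipse_footprint, project_max, preprocess,
                                 close_gray, otsu_value, backproject)


def brute_force_otsu(img, nbins=None):
    """Exhaustive between-class-variance maximization over gray levels."""
    a = np.asarray(img).ravel().astype(float)
    levels = np.unique(a)
    best_t, best_s = None, -np.inf
    for t in levels[:-1]:
        c0, c1 = a[a <= t], a[a > t]
        w0, w1 = len(c0) / len(a), len(c1) / len(a)
        s = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if s > best_s + 1e-12:
            best_s, best_t = s, t
    return best_t


def scipy_closing(img, r0, r1):
    """Sliding-window max/min closing with the same pad-with-minimum
    border convention as the implementation (independent oracle)."""
    fp = ellipse_footprint(r0, r1)
    img = np.asarray(img, dtype=float)
    padded = np.pad(img, ((2 * r0,), (2 * r1,)), constant_values=img.min())
    dil = ndi.maximum_filter(padded, footprint=fp, mode="constant", cval=-np.inf)
    closed = ndi.minimum_filter(dil, footprint=fp, mode="constant", cval=np.inf)
    return closed[2 * r0: closed.shape[0] - 2 * r0, 2 * r1: closed.shape[1] - 2 * r1]


class TestProjectMax:
    def test_constant_and_single_voxel(self):
        stack = sf.ImageStack(np.full((4, 5, 6), 7, np.uint8))
        p = project_max(stack)
        assert p.i_xy.shape == (4, 5) and p.i_xz.shape == (4, 6) and p.i_yz.shape == (5, 6)
        assert np.all(p.i_xy == 7) and np.all(p.i_xz == 7) and np.all(p.i_yz == 7)
        data = np.zeros((4, 5, 6), np.uint8)
        data[1, 2, 3] = 9
        p = project_max(sf.ImageStack(data))
        assert p.i_xy[1, 2] == 9 and p.i_xz[1, 3] == 9 and p.i_yz[2, 3] == 9
        assert p.i_xy.sum() == 9

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 255, (6, 7, 5)).astype(np.uint8)
        p = project_max(sf.ImageStack(data))
        for i in range(6):
            for j in range(7):
                assert p.i_xy[i, j] == max(data[i, j, k] for k in range(5))
            for k in range(5):
                assert p.i_xz[i, k] == max(data[i, j, k] for j in range(7))


class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 5.0)
        assert np.array_equal(preprocess(img, 0.0, (1, 1)), img)

    def test_gaussian_mass_conserved(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        sm = preprocess(img, 2.0, (1, 1), stretch=False)
        assert abs(sm.sum() - 1.0) < 1e-6

    def test_two_level_stretch_maps_to_full_range(self):
        img = np.where(np.arange(100).reshape(10, 10) < 50, 10.0, 200.0)
        out = preprocess(img, 0.0, (1, 1))
        assert out.min() == 0.0 and out.max() == 1.0
        assert set(np.unique(out)) == {0.0, 1.0}


class TestTemplateScales:
    @pytest.mark.parametrize("args,expected", [
        ((21, 12, 2), [21, 19, 17, 15, 13, 12]),
        ((21, 21, 2), [21]),
        ((20, 12, 4), [20, 16, 12]),
    ])
    def test_ladder(self, args, expected):
        assert sf.template_scales(*args) == expected


class TestCloseGray:
    def test_constant_unchanged(self):
        img = np.full((30, 30), 3.0)
        assert np.allclose(close_gray(img, 5.0, (1, 1)), img)

    def test_fills_small_dark_hole(self):
        img = np.zeros((40, 40))
        yy, xx = np.mgrid[:40, :40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15 ** 2
        img[disk] = 1.0
        img[18:22, 18:22] = 0.0  # 4-px hole, smaller than the template
        closed = close_gray(img, 9.0, (1, 1))
        assert np.all(closed[18:22, 18:22] == 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_footprint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((40, 33))
        # diameter 7 um at (1, 1.4) um pixels -> anisotropic radii (4, 2)
        mine = close_gray(img, 7.0, (1.0, 1.4))
        assert np.allclose(mine, scipy_closing(img, 4, 2))

    def test_extensive_idempotent_monotone(self):
        rng = np.random.default_rng(3)
        a = rng.random((30, 30))
        b = a + rng.random((30, 30))  # b >= a everywhere
        ca, cb = close_gray(a, 5.0, (1, 1)), close_gray(b, 5.0, (1, 1))
        assert np.all(ca >= a - 1e-12)
        assert np.allclose(close_gray(ca, 5.0, (1, 1)), ca)
        assert np.all(cb >= ca - 1e-12)

    def test_oversized_template_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            close_gray(np.zeros((10, 10)), 30.0, (1, 1))


class TestOtsu:
    def test_separable_bimodal(self):
        img = np.concatenate([np.full(50, 10), np.full(50, 200)]).astype(
            np.uint8).reshape(10, 10)
        b = sf.otsu_threshold(img)
        assert b.sum() == 50 and np.all(img[b] == 200)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        assert otsu_value(img) == brute_force_otsu(img)

    def test_matches_skimage(self):
        from skimage.filters import threshold_otsu
        rng = np.random.default_rng(8)
        img = rng.integers(0, 255, (32, 32)).astype(np.uint8)
        mine = sf.otsu_threshold(img)
        theirs = img > threshold_otsu(img)
        assert np.array_equal(mine, theirs)

    def test_inversion_gives_complementary_classes(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 255, (20, 20)).astype(np.uint8)
        fg = sf.otsu_threshold(img)
        fg_inv = sf.otsu_threshold(255 - img)
        # foreground of the inverted image is (a subset of) the original background
        assert not np.any(fg & fg_inv)
        assert (fg.sum() + fg_inv.sum()) >= img.size - np.isin(
            img, [otsu_value(img), 255 - otsu_value(255 - img)]).sum()

    def test_constant_image_warns_all_background(self):
        with pytest.warns(UserWarning, match="constant"):
            b = sf.otsu_threshold(np.full((5, 5), 9, np.uint8))
        assert not b.any()


class TestBackproject:
    def test_full_and_single_pixel(self):
        full = np.ones((2, 2), bool)
        assert backproject(full, full, full).all()
        bxy = np.zeros((3, 4), bool); bxy[1, 2] = True
        bxz = np.zeros((3, 5), bool); bxz[1, 0] = True
        byz = np.zeros((4, 5), bool); byz[2, 0] = True
        v = backproject(bxy, bxz, byz)
        assert v.sum() == 1 and v[1, 2, 0]

    def test_matches_membership_oracle(self):
        rng = np.random.default_rng(5)
        bxy = rng.random((5, 6)) < 0.3
        bxz = rng.random((5, 4)) < 0.3
        byz = rng.random((6, 4)) < 0.3
        v = backproject(bxy, bxz, byz)
        for x in range(5):
            for y in range(6):
                for z in range(4):
                    assert v[x, y, z] == (bxy[x, y] and bxz[x, z] and byz[y, z])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            backproject(np.ones((3, 3), bool), np.ones((4, 3), bool),
                        np.ones((3, 3), bool))


class TestFindCandidates:
    def test_background_only_gives_nothing(self, params):
        stack = sf.ImageStack(np.full((100, 100, 40), 30, np.uint8))
        with pytest.warns(UserWarning, match="constant"):
            assert sf.find_candidates(stack, params) == []

    def test_solid_soma_detected_at_max_scale(self, params, solid_soma_phantom):
        stack, truth = solid_soma_phantom
        scales = []
        cands = sf.find_candidates(stack, params,
                                   on_scale=lambda s, n: scales.append(s))
        assert len(cands) == 1
        assert cands[0].scale_um == 21.0
        assert scales == [21.0]  # early termination: no smaller scale evaluated
        err = np.linalg.norm(np.asarray(cands[0].centroid_um) - truth.centroids_um[0])
        assert err <= 2.0

    def test_hollow_soma_single_component(self, params, hollow_soma_phantom):
        """Interior hollowness must not split or displace the detection."""
        stack, truth = hollow_soma_phantom
        cands = sf.find_candidates(stack, params)
        assert len(cands) == 1
        labeled, n = ndi.label(cands[0].mask, np.ones((3, 3, 3)))
        assert n == 1
        err = np.linalg.norm(np.asarray(cands[0].centroid_um) - truth.centroids_um[0])
        assert err <= 2.0

    def test_hull_superset_of_truth(self, params, solid_soma_phantom):
        """Backprojection superset property: the ground-truth soma lies
        inside its detected volume intersection."""
        stack, truth = solid_soma_phantom
        cand = sf.find_candidates(stack, params)[0]
        t = truth.somas[0]
        hull = np.zeros(stack.shape, bool)
        lo = np.asarray(cand.mask_lo_vox)
        hull[lo[0]:lo[0] + cand.mask.shape[0],
             lo[1]:lo[1] + cand.mask.shape[1],
             lo[2]:lo[2] + cand.mask.shape[2]] = cand.mask
        tlo = np.asarray(t.mask_lo_vox)
        tvox = np.argwhere(t.mask) + tlo
        inside = hull[tvox[:, 0], tvox[:, 1], tvox[:, 2]]
        assert inside.mean() > 0.99
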