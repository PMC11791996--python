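"""Similarity transforms and diffeomorphic b-spline fields."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

import valvemesh as vm
from valvemesh.deformation import (BSplineDiffeo, SimilarityTransform,
                                   bending_energy, coarse_view,
                                   densify_velocity, integrate_velocity,
                                   jacobian_determinant, warp_points)

AFFINE2 = np.diag([2.0, 2.0, 2.0, 1.0])


def smooth_field(shape, seed, amplitude_mm, control_spacing=3):
    f = BSplineDiffeo.zeros(shape, AFFINE2, control_spacing)
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=f.velocity.shape)
    for c in range(3):
        raw[c] = gaussian_filter(raw[c], 1.0)
    f.velocity = raw / np.abs(raw).max() * amplitude_mm
    return f


def cubic_bspline(t):
    t = abs(t)
    if t < 1:
        return 2 / 3 - t**2 + t**3 / 2
    if t < 2:
        return (2 - t) ** 3 / 6
    return 0.0


class TestSimilarityTransform:
    def test_identity(self):
        s = SimilarityTransform()
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert np.allclose(s.apply(pts), pts)

    def test_matches_homogeneous_matrix_oracle(self, rng):
        s = SimilarityTransform(rotation=[0.2, -0.4, 0.1],
                                translation=[3, -2, 7],
                                scale=[1.1, 0.8, 1.3], center=[5, 5, 5])
        cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                         for z in (0, 1)], dtype=float) * 10
        hom = np.column_stack([cube, np.ones(8)])
        expect = (hom @ s.matrix().T)[:, :3]
        assert np.allclose(s.apply(cube), expect, atol=1e-12)

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            SimilarityTransform(scale=[1, -1, 1])

    def test_json_roundtrip(self, tmp_path):
        s = SimilarityTransform([0.1, 0, 0], [1, 2, 3], [1.2, 1, 0.9])
        p = str(tmp_path / "sim.json")
        s.to_json(p)
        back = SimilarityTransform.from_json(p)
        pts = np.random.default_rng(1).normal(size=(5, 3))
        assert np.allclose(s.apply(pts), back.apply(pts))


class TestDensify:
    def test_zero_controls(self):
        f = BSplineDiffeo.zeros((8, 9, 10), AFFINE2)
        assert np.all(densify_velocity(f) == 0)

    def test_constant_reproduced(self):
        f = BSplineDiffeo.zeros((8, 9, 10), AFFINE2)
        f.velocity[:] = np.array([1.5, -2.0, 0.7])[:, None, None, None]
        dense = densify_velocity(f)
        assert np.allclose(dense, f.velocity[:, :1, :1, :1], atol=1e-12)

    def test_matches_tensor_product_basis_sum(self, rng):
        f = BSplineDiffeo.zeros((12, 13, 11), AFFINE2)
        f.velocity = rng.normal(size=f.velocity.shape)
        dense = densify_velocity(f)
        i, j, k = 5, 7, 3
        u = np.array([i, j, k]) / 3 + 1
        val = np.zeros(3)
        nc = f.velocity.shape[1:]
        for a in range(nc[0]):
            for b in range(nc[1]):
                for c in range(nc[2]):
                    w = (cubic_bspline(u[0] - a) * cubic_bspline(u[1] - b)
                         * cubic_bspline(u[2] - c))
                    if w:
                        val += w * f.velocity[:, a, b, c]
        assert np.allclose(dense[:, i, j, k], val, atol=1e-12)

    def test_lattice_mismatch_rejected(self):
        with pytest.raises(ValueError):
            BSplineDiffeo(np.zeros((3, 2, 2, 2)), (20, 20, 20), AFFINE2)


class TestIntegrate:
    def test_zero_velocity_is_identity(self):
        f = BSplineDiffeo.zeros((10, 10, 10), AFFINE2)
        assert np.all(integrate_velocity(f) == 0)

    def test_constant_velocity_is_translation(self):
        f = BSplineDiffeo.zeros((10, 10, 10), AFFINE2)
        f.velocity[:] = np.array([1.5, -2.0, 0.7])[:, None, None, None]
        disp = integrate_velocity(f)
        assert np.allclose(disp, f.velocity[:, :1, :1, :1], atol=1e-9)

    def test_matches_fine_step_euler_flow(self):
        f = smooth_field((24, 24, 24), seed=3, amplitude_mm=1.0)
        disp = integrate_velocity(f) / 2.0  # voxel units
        dense_v = densify_velocity(f) / 2.0
        grid = list(np.meshgrid(*[np.arange(24.0)] * 3, indexing="ij"))
        u = np.zeros_like(dense_v)
        n = 100
        for _ in range(n):
            vv = np.empty_like(u)
            for c in range(3):
                vv[c] = map_coordinates(dense_v[c],
                                        [grid[a] + u[a] for a in range(3)],
                                        order=1, mode="nearest")
            u = u + vv / n
        core = (slice(None), slice(3, -3), slice(3, -3), slice(3, -3))
        rel = (np.linalg.norm((disp - u)[core], axis=0).max()
               / np.linalg.norm(u, axis=0).max())
        assert rel < 0.01

    @pytest.mark.parametrize("seed", range(3))
    def test_positive_jacobian_and_inverse_consistency(self, seed):
        f = smooth_field((32, 32, 32), seed=seed, amplitude_mm=4.0)
        disp = integrate_velocity(f) / 2.0
        jac = jacobian_determinant(disp * 2.0, 2.0)
        assert jac[1:-1, 1:-1, 1:-1].min() > 0
        fneg = BSplineDiffeo(-f.velocity, f.shape, f.affine, 3)
        dneg = integrate_velocity(fneg) / 2.0
        grid = list(np.meshgrid(*[np.arange(32.0)] * 3, indexing="ij"))
        resid = disp.copy()
        for c in range(3):
            resid[c] += map_coordinates(dneg[c],
                                        [grid[a] + disp[a] for a in range(3)],
                                        order=1, mode="nearest")
        err = np.linalg.norm(resid, axis=0)[2:-2, 2:-2, 2:-2].max()
        assert err <= 0.1  # voxels

    def test_coarse_view_same_continuous_field(self):
        f = smooth_field((31, 31, 31), seed=5, amplitude_mm=2.0)
        cv = coarse_view(f)
        dense_f = densify_velocity(f)
        dense_c = densify_velocity(cv)
        # coarse lattice points sit on every 3rd fine voxel
        assert np.allclose(dense_c, dense_f[:, ::3, ::3, ::3], atol=1e-12)


class TestWarpPoints:
    def test_identity(self, template):
        out = warp_points(template.nodes, SimilarityTransform(), None)
        assert np.allclose(out, template.nodes)

    def test_pure_translation(self, rng):
        pts = rng.normal(size=(20, 3))
        s = SimilarityTransform(translation=[4, -1, 2])
        assert np.allclose(warp_points(pts, s), pts + [4, -1, 2])

    def test_similarity_then_diffeo_composition_order(self):
        f = BSplineDiffeo.zeros((16, 16, 16), AFFINE2)
        f.velocity[:] = np.array([0.0, 0.0, 1.0])[:, None, None, None]
        s = SimilarityTransform(translation=[2, 0, 0])
        pts = np.array([[10.0, 10.0, 10.0]])
        out = warp_points(pts, s, f)
        assert np.allclose(out, [[12.0, 10.0, 11.0]], atol=1e-9)


class TestBendingEnergy:
    def test_zero_field(self):
        assert bending_energy(np.zeros((3, 8, 8, 8))) == 0.0

    def test_affine_field_has_zero_bending(self, rng):
        x = np.arange(10.0)
        phi = np.zeros((3, 10, 10, 10))
        A = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        for c in range(3):
            phi[c] = (A[c, 0] * x[:, None, None] + A[c, 1] * x[None, :, None]
                      + A[c, 2] * x[None, None, :] + b[c])
        assert bending_energy(phi) < 1e-24

    def test_quadratic_field_value(self):
        x = np.arange(12.0)
        phi = np.zeros((3, 12, 12, 12))
        phi[0] = (x**2)[:, None, None]
        assert np.isclose(bending_energy(phi), 4.0)

    def test_matches_stencil_loop_oracle(self, rng):
        phi = rng.normal(size=(3, 6, 6, 6))

        def d2(a, axis):
            a = np.moveaxis(a, axis, 0)
            out = np.empty_like(a)
            out[1:-1] = a[2:] - 2 * a[1:-1] + a[:-2]
            out[0] = a[0] - 2 * a[1] + a[2]
            out[-1] = a[-1] - 2 * a[-2] + a[-3]
            return np.moveaxis(out, 0, axis)

        total = 0.0
        for c in range(3):
            first = np.gradient(phi[c])
            for a in range(3):
                for b in range(a, 3):
                    if a == b:
                        total += np.sum(d2(phi[c], a) ** 2)
                    else:
                        total += 2 * np.sum(np.gradient(first[a], axis=b) ** 2)
        total /= phi[0].size
        assert np.isclose(bending_energy(phi), total, rtol=1e-12)

    def test_invariant_under_adding_affine(self, rng):
        f = smooth_field((16, 16, 16), seed=9, amplitude_mm=1.0)
        phi = integrate_velocity(f) / 2.0
        base = bending_energy(phi)
        x = np.arange(16.0)
        aff = np.zeros_like(phi)
        aff[1] = 0.3 * x[:, None, None] - 0.2 * x[None, None, :] + 1.0
        assert np.isclose(bending_energy(phi + aff), base, rtol=1e-9)

    def test_too_small_domain_rejected(self):
        with pytest.raises(ValueError):
            bending_energy(np.zeros((3, 2, 5, 5)))


def test_displacement_nifti_roundtrip(tmp_path):
    f = smooth_field((12, 12, 12), seed=1, amplitude_mm=1.0)
    p = str(tmp_path / "disp.nii.gz")
    f.save_displacement(p)
    import nibabel as nib
    back = np.moveaxis(np.asarray(nib.load(p).dataobj), -1, 0)
    assert np.allclose(back, integrate_velocity(f), atol=1e-5)
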