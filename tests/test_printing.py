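"""Print-conversion chain: stencil, SDF, isosurface, remesh, merge."""

import numpy as np
import pytest
import trimesh

import valvemesh as vm
from valvemesh.printing import (cap_boundary_loops, component_surface_trimesh,
                                convert_component, measure_thickness,
                                merge_two_phase, mesh_sdf, offset_surface,
                                remesh_uniform, sdf_from_segmentation,
                                smooth_surface, stencil_voxelize,
                                watertight_check, _junction_rim)
from valvemesh.images import axis_aligned_image


@pytest.fixture(scope="module")
def sphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


def open_tube(radius, z0, z1, n_theta=32, n_z=10, cap="top"):
    th = np.arange(n_theta) * 2 * np.pi / n_theta
    zs = np.linspace(z0, z1, n_z + 1)
    verts = np.array([[radius * np.cos(a), radius * np.sin(a), z]
                      for z in zs for a in th])
    faces = []
    for iz in range(n_z):
        for it in range(n_theta):
            a = iz * n_theta + it
            b = iz * n_theta + (it + 1) % n_theta
            c = (iz + 1) * n_theta + (it + 1) % n_theta
            d = (iz + 1) * n_theta + it
            faces += [[a, b, c], [a, c, d]]
    nv = len(verts)
    if cap == "top":
        verts = np.vstack([verts, [0, 0, z1]])
        faces += [[n_z * n_theta + it, n_z * n_theta + (it + 1) % n_theta, nv]
                  for it in range(n_theta)]
    else:
        verts = np.vstack([verts, [0, 0, z0]])
        faces += [[(it + 1) % n_theta, it, nv] for it in range(n_theta)]
    m = trimesh.Trimesh(verts, faces, process=False)
    trimesh.repair.fix_normals(m)
    return m


class TestStencil:
    def test_sphere_volume_within_two_percent(self, sphere):
        seg = stencil_voxelize(sphere, 0.5)
        vol = seg.values.sum() * 0.5**3
        assert abs(vol - 4 / 3 * np.pi * 1000) / (4 / 3 * np.pi * 1000) < 0.02

    def test_box_exact_lattice_count(self):
        box = trimesh.creation.box(extents=[4.3, 3.3, 5.3])
        seg = stencil_voxelize(box, 1.0)
        # lattice points with centre strictly inside the box
        idx = np.indices(seg.shape).reshape(3, -1).T
        centers = seg.voxel_to_world(idx.astype(float))
        inside = np.all(np.abs(centers) < np.array([2.15, 1.65, 2.65]),
                        axis=1)
        assert seg.values.sum() == inside.sum()

    def test_open_surface_rejected(self, sphere):
        holed = trimesh.Trimesh(sphere.vertices, sphere.faces[1:],
                                process=False)
        with pytest.raises(ValueError):
            stencil_voxelize(holed, 0.5)


class TestSdf:
    def test_half_space_ramp(self):
        seg = axis_aligned_image(np.zeros((20, 8, 8)), 1.0)
        seg.values[:10] = 1.0
        sdf = sdf_from_segmentation(seg).grid.values
        # linear ramps away from the interface between voxels 9 and 10
        assert np.allclose(sdf[10:, 4, 4], np.arange(1, 11))
        assert np.allclose(sdf[:10, 4, 4], -np.arange(10, 0, -1))

    def test_sphere_center_depth(self, sphere):
        seg = stencil_voxelize(sphere, 0.5)
        sdf = sdf_from_segmentation(seg)
        ci = np.round(seg.world_to_voxel(np.zeros(3))[0]).astype(int)
        assert sdf.grid.values[tuple(ci)] == pytest.approx(-10.0, abs=0.5)

    def test_matches_bruteforce_nearest_boundary(self, rng):
        seg = axis_aligned_image(np.zeros((16, 16, 16)), 1.0)
        blob = rng.random((16, 16, 16)) > 0.8
        from scipy.ndimage import binary_dilation
        blob = binary_dilation(blob)
        blob[0] = blob[-1] = False
        seg.values[...] = blob
        sdf = sdf_from_segmentation(seg).grid.values
        idx = np.indices(seg.shape).reshape(3, -1).T
        fg = idx[blob.ravel()]
        bg = idx[~blob.ravel()]
        for p in idx[rng.choice(len(idx), 40)]:
            if blob[tuple(p)]:
                expect = -np.sqrt(((bg - p) ** 2).sum(axis=1).min())
            else:
                expect = np.sqrt(((fg - p) ** 2).sum(axis=1).min())
            assert sdf[tuple(p)] == pytest.approx(expect, rel=1e-12)

    def test_uniform_masks_rejected(self):
        seg = axis_aligned_image(np.ones((4, 4, 4)), 1.0)
        with pytest.raises(ValueError):
            sdf_from_segmentation(seg)
        seg.values[...] = 0.0
        with pytest.raises(ValueError):
            sdf_from_segmentation(seg)


class TestOffsetSurface:
    def test_zero_level_recovers_radius(self, sphere):
        sdf = mesh_sdf(sphere, 0.5)
        m = offset_surface(sdf, 0.0)
        r = np.linalg.norm(m.vertices, axis=1)
        assert abs(r.mean() - 10.0) < 0.5
        assert m.is_watertight

    def test_positive_level_offsets_outward(self, sphere):
        sdf = mesh_sdf(sphere, 0.5)
        m = offset_surface(sdf, 1.0)
        r = np.linalg.norm(m.vertices, axis=1)
        assert abs(r.mean() - 11.0) < 0.5

    def test_level_beyond_range_rejected(self, sphere):
        sdf = mesh_sdf(sphere, 0.5)
        with pytest.raises(ValueError):
            offset_surface(sdf, 1e4)


class TestRemesh:
    def test_same_count_preserves_geometry(self, sphere):
        out = remesh_uniform(sphere, len(sphere.vertices))
        assert 0.9 <= len(out.vertices) / len(sphere.vertices) <= 1.1
        assert out.is_watertight
        r = np.linalg.norm(out.vertices, axis=1)
        assert np.abs(r - 10.0).max() < 0.2  # 2% of radius

    def test_coarsen_watertight_volume_preserved(self, sphere):
        out = remesh_uniform(sphere, len(sphere.vertices) // 4)
        assert out.is_watertight
        assert abs(out.volume - sphere.volume) / sphere.volume < 0.02
        # triangle quality: 2 * inradius / circumradius bounded away from 0
        a = np.linalg.norm(out.triangles[:, 1] - out.triangles[:, 0], axis=1)
        b = np.linalg.norm(out.triangles[:, 2] - out.triangles[:, 1], axis=1)
        c = np.linalg.norm(out.triangles[:, 0] - out.triangles[:, 2], axis=1)
        s = (a + b + c) / 2
        q = 2 * (out.area_faces / s) / (a * b * c / (4 * out.area_faces))
        assert q.min() > 0.05

    def test_uniformity_improves_on_graded_input(self, sphere):
        graded = sphere.copy()
        # grade the mesh: pull vertices toward a pole tangentially
        v = graded.vertices.copy()
        t = (v[:, 2] / 10.0 + 1) / 2
        v[:, :2] *= (0.4 + 0.6 * t)[:, None]
        v *= 10.0 / np.linalg.norm(v, axis=1)[:, None]
        graded = trimesh.Trimesh(v, graded.faces, process=False)

        def edge_cv(m):
            e = np.linalg.norm(m.vertices[m.edges_unique[:, 0]]
                               - m.vertices[m.edges_unique[:, 1]], axis=1)
            return e.std() / e.mean()

        out = remesh_uniform(graded, len(graded.vertices))
        assert edge_cv(out) < edge_cv(graded)

    def test_nonmanifold_rejected(self, sphere):
        bad = trimesh.Trimesh(sphere.vertices, sphere.faces[:-5],
                              process=False)
        with pytest.raises(ValueError):
            remesh_uniform(bad, 100)


class TestSmoothing:
    def test_zero_iterations_identity(self, sphere):
        out = smooth_surface(sphere, 0)
        assert np.array_equal(out.vertices, sphere.vertices)

    def test_smooth_sphere_volume_stable(self, sphere):
        out = smooth_surface(sphere, 10)
        assert abs(out.volume - sphere.volume) / sphere.volume < 0.01

    def test_noise_reduction(self, sphere, rng):
        noisy = sphere.copy()
        noisy.vertices += rng.normal(0, 0.2, noisy.vertices.shape)

        def rms(m):
            return np.sqrt(np.mean(
                (np.linalg.norm(m.vertices, axis=1) - 10.0) ** 2))

        out = smooth_surface(noisy, 15)
        assert rms(out) <= 0.5 * rms(noisy)
        assert abs(out.volume - sphere.volume) / sphere.volume < 0.03


class TestWatertightCheck:
    def test_icosphere_passes(self, sphere):
        rep = watertight_check(sphere, check_self_intersections=False)
        assert rep.passed and rep.boundary_edges == 0

    def test_missing_face_reports_boundary(self, sphere):
        holed = trimesh.Trimesh(sphere.vertices, sphere.faces[1:],
                                process=False)
        rep = watertight_check(holed, check_self_intersections=False)
        assert not rep.watertight and rep.boundary_edges == 3

    def test_intersecting_spheres_detected(self):
        # generic pose: a shifted, slightly rotated copy (exact-symmetry
        # poses cross edge-on-edge, which the strict predicate excludes)
        a = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        b = a.copy()
        b.apply_transform(trimesh.transformations.rotation_matrix(
            0.3, [0.2, 1.0, 0.4]))
        b.apply_translation([8.0, 0.7, 0.3])
        both = trimesh.util.concatenate([a, b])
        rep = watertight_check(both)
        assert rep.self_intersections > 0


class TestConvertComponent:
    def test_leaflet_thickness_and_consistency(self, template):
        surf = component_surface_trimesh(template, "leaflet1")
        pm = convert_component("leaflet", surface=surf,
                               target_thickness_mm=0.6,
                               native_thickness_mm=0.9)
        assert pm.watertight
        assert pm.mesh.faces.shape[1] == 3
        th = measure_thickness(pm.mesh, 300)
        assert abs(th - 0.6) <= 0.25
        from valvemesh.quality import normalized_chamfer
        from valvemesh.mesh import sample_triangles
        p1, _ = sample_triangles(np.asarray(pm.mesh.vertices),
                                 np.asarray(pm.mesh.faces),
                                 1500 / pm.mesh.area)
        p2, _ = sample_triangles(np.asarray(surf.vertices),
                                 np.asarray(surf.faces), 1500 / surf.area)
        cd = normalized_chamfer(p1, p2, root_mean=True)
        assert cd <= 2 * 0.25 + 0.15  # two voxels + the erosion offset

    def test_thickness_monotone_in_target(self, template):
        surf = component_surface_trimesh(template, "leaflet2")
        th = [measure_thickness(
            convert_component("leaflet", surface=surf,
                              target_thickness_mm=t,
                              native_thickness_mm=0.9).mesh, 200)
            for t in (0.6, 1.0, 1.4)]
        assert th[0] < th[1] < th[2]

    def test_below_printer_minimum_warns_and_thickens(self, template):
        surf = component_surface_trimesh(template, "leaflet3")
        with pytest.warns(UserWarning):
            pm = convert_component("leaflet", surface=surf,
                                   target_thickness_mm=0.3,
                                   native_thickness_mm=0.9)
        assert pm.target_thickness_mm == 0.6

    def test_calcification_volume_and_watertightness(self, spec, template):
        calc = vm.make_calcification(spec, template)
        pm = convert_component("calcification", segmentation=calc)
        assert pm.watertight
        vol_vox = calc.grid.values.sum() * 0.33**3
        assert abs(pm.mesh.volume - vol_vox) / vol_vox < 0.10

    def test_wall_offset_zero_consistency(self):
        # small sphere as an inner wall; the inner shell surface of the
        # conversion must stay within a millimetre of the input
        sph = trimesh.creation.icosphere(subdivisions=3, radius=12.0)
        pm = convert_component("wall", surface=sph, target_thickness_mm=1.3)
        assert pm.watertight
        r = np.linalg.norm(pm.mesh.vertices, axis=1)
        assert abs(r.min() - 12.0) < 1.0      # inner shell at the input
        assert abs(r.max() - 13.3) < 1.0      # outer shell offset by 1.3
        th = measure_thickness(pm.mesh, 300)
        assert abs(th - 1.3) <= 0.5           # one voxel at 0.5 mm


class TestMergeTwoPhase:
    def test_continuous_inputs_stay_put(self):
        aorta = open_tube(10.0, 2.0, 32.0, cap="top")
        lv = open_tube(10.0, -32.0, 0.0, cap="bottom")
        res = merge_two_phase(aorta, lv, iters=400)
        all0 = np.vstack([aorta.vertices, lv.vertices])
        move = np.linalg.norm(res.mesh.vertices[res.transition_vertices]
                              - all0[res.transition_vertices], axis=1).max()
        assert move < 1.0
        assert np.linalg.norm(res.rigid_a.translation) < 0.5
        assert np.linalg.norm(res.rigid_b.translation) < 0.5

    def test_lateral_gap_closed_rigidly(self):
        aorta = open_tube(10.0, 2.0, 32.0, cap="top")
        lv = open_tube(10.0, -32.0, 0.0, cap="bottom")
        lv.vertices[:, 0] += 5.0
        loop_a = _junction_rim(aorta, lv.vertices.mean(axis=0))
        loop_b = _junction_rim(lv, aorta.vertices.mean(axis=0))
        na = len(aorta.vertices)
        res = merge_two_phase(aorta, lv, iters=800)
        v = res.mesh.vertices
        ca, cb = v[loop_a].mean(axis=0), v[loop_b + na].mean(axis=0)
        assert np.linalg.norm((ca - cb)[:2]) < 0.5
        # non-transition pairwise distances preserved to 1e-6 relative
        rng = np.random.default_rng(0)
        nonfree = np.setdiff1d(np.arange(na), res.transition_vertices)
        ii, jj = rng.choice(nonfree, 50), rng.choice(nonfree, 50)
        d0 = np.linalg.norm(aorta.vertices[ii] - aorta.vertices[jj], axis=1)
        d1 = np.linalg.norm(v[ii] - v[jj], axis=1)
        assert np.abs(d1 - d0).max() / d0.max() < 1e-6
        # single connected surface
        assert res.mesh.body_count == 1

    def test_edge_dominant_limit_preserves_ratios(self):
        aorta = open_tube(10.0, 2.0, 32.0, cap="top")
        lv = open_tube(10.0, -32.0, 0.0, cap="bottom")
        res = merge_two_phase(aorta, lv, lambdas=(10.0, 1.0, 1e6),
                              iters=900)
        # intra-side edges: length ratios preserved vs the initial config
        v0 = np.vstack([aorta.vertices, lv.vertices])
        v1 = res.mesh.vertices
        edges = res.mesh.edges_unique
        na = len(aorta.vertices)
        intra = (edges[:, 0] < na) == (edges[:, 1] < na)
        l0 = np.linalg.norm(v0[edges[intra, 0]] - v0[edges[intra, 1]], axis=1)
        l1 = np.linalg.norm(v1[edges[intra, 0]] - v1[edges[intra, 1]], axis=1)
        assert np.abs(l1 / l1.max() - l0 / l0.max()).max() < 1e-4

    def test_far_apart_phases_rejected(self):
        aorta = open_tube(10.0, 60.0, 90.0, cap="top")
        lv = open_tube(10.0, -32.0, 0.0, cap="bottom")
        with pytest.raises(ValueError):
            merge_two_phase(aorta, lv)

    def test_capped_merge_is_closed(self):
        aorta = open_tube(10.0, 2.0, 32.0, cap="top")
        lv = open_tube(10.0, -32.0, 0.0, cap="bottom")
        res = merge_two_phase(aorta, lv, iters=200)
        closed = cap_boundary_loops(res.mesh)
        assert watertight_check(closed,
                                check_self_intersections=False).watertight
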