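"""Loss terms: closed forms, brute-force oracles, gradients, invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import valvemesh as vm
from valvemesh.energies import (LossWeights, arap_energy_grad,
                                asqrt_energy_grad, chamfer_loss,
                                chamfer_loss_grad, deformation_gradient,
                                dice_loss, edge_length_correspondence,
                                edge_length_correspondence_grad,
                                laplacian_preservation_grad,
                                laplacian_smoothness,
                                laplacian_smoothness_grad,
                                normal_consistency, normal_consistency_grad,
                                normal_preservation_grad, soft_dice,
                                total_mesh_loss, triangle_adjacency)


def random_rigid(rng):
    R = Rotation.from_rotvec(rng.normal(0, 0.8, 3)).as_matrix()
    t = rng.normal(0, 10, 3)
    return R, t


class TestChamfer:
    def test_identical_sets_zero(self, rng):
        A = rng.normal(size=(30, 3))
        assert chamfer_loss(A, A) == 0.0

    def test_hand_case(self):
        assert chamfer_loss(np.zeros((1, 3)),
                            np.array([[1.0, 0, 0]])) == pytest.approx(2.0)

    def test_symmetric(self, rng):
        A, B = rng.normal(size=(40, 3)), rng.normal(size=(55, 3))
        assert chamfer_loss(A, B) == pytest.approx(chamfer_loss(B, A),
                                                   rel=1e-12)

    def test_matches_exhaustive_all_pairs_oracle(self, rng):
        A = rng.normal(size=(50, 3)) * 5
        B = rng.normal(size=(60, 3)) * 5
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
        expect = d2.min(axis=1).mean() + d2.min(axis=0).mean()
        assert chamfer_loss(A, B) == pytest.approx(expect, rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            chamfer_loss(np.zeros((0, 3)), np.zeros((3, 3)))


class TestDeformationGradient:
    def test_rigid_motion_gives_rotation(self, template, rng):
        R, t = random_rigid(rng)
        hexes = template.all_hexes()
        F, Rk, _, _ = deformation_gradient(template.nodes,
                                           template.nodes @ R.T + t, hexes)
        assert np.allclose(F, R, atol=1e-8)
        assert np.allclose(Rk, R, atol=1e-8)

    def test_isotropic_scaling(self, template):
        hexes = template.all_hexes()
        F, Rk, _, _ = deformation_gradient(template.nodes,
                                           template.nodes * 3.0, hexes)
        assert np.allclose(F, 3.0 * np.eye(3), atol=1e-8)
        assert np.allclose(Rk, np.eye(3), atol=1e-8)

    def test_polar_factor_matches_svd_oracle(self, template, rng):
        hexes = template.all_hexes()[:20]
        nodes_def = template.nodes + rng.normal(0, 0.3, template.nodes.shape)
        F, Rk, _, _ = deformation_gradient(template.nodes, nodes_def, hexes)
        for f, r in zip(F, Rk):
            U, _, Vt = np.linalg.svd(f)
            d = np.sign(np.linalg.det(U @ Vt))
            expect = U @ np.diag([1, 1, d]) @ Vt
            assert np.allclose(r, expect, atol=1e-10)
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-8)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_reference_rejected(self):
        nodes = np.zeros((8, 3))
        nodes[:, 0] = np.arange(8)  # rank-1 element
        with pytest.raises(ValueError):
            deformation_gradient(nodes, nodes, np.arange(8)[None, :])


class TestDistortionEnergies:
    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_nullity(self, template, seed):
        rng = np.random.default_rng(seed)
        R, t = random_rigid(rng)
        moved = template.with_nodes(template.nodes @ R.T + t)
        assert vm.arap_energy(template, moved) < 1e-8
        assert vm.asqrt_energy(template, moved) < 1e-8

    @pytest.mark.parametrize("s", [0.5, 1.3, 2.0])
    def test_uniform_scaling_closed_forms(self, template, s):
        scaled = template.with_nodes(template.nodes * s)
        assert vm.arap_energy(template, scaled) == pytest.approx(
            3 * (s - 1) ** 2, rel=1e-10, abs=1e-12)
        assert vm.asqrt_energy(template, scaled) == pytest.approx(
            (s - 1) ** 2, rel=1e-10, abs=1e-12)

    def test_matches_per_element_loop_oracle(self, template, rng):
        nodes_def = template.nodes + rng.normal(0, 0.4, template.nodes.shape)
        deformed = template.with_nodes(nodes_def)
        hexes = template.all_hexes()
        d_all = template.all_anisotropy()
        arap_sum = asqrt_sum = 0.0
        for el, d in zip(hexes, d_all):
            X = template.nodes[el] - template.nodes[el].mean(axis=0)
            x = nodes_def[el] - nodes_def[el].mean(axis=0)
            F = (x.T @ X) @ np.linalg.inv(X.T @ X)
            U, _, Vt = np.linalg.svd(F)
            sgn = np.sign(np.linalg.det(U @ Vt))
            R = U @ np.diag([1, 1, sgn]) @ Vt
            arap_sum += np.sum((F - R) ** 2)
            asqrt_sum += (np.sqrt(d @ F.T @ F @ d) - 1) ** 2
        assert vm.arap_energy(template, deformed) == pytest.approx(
            arap_sum / len(hexes), rel=1e-10)
        assert vm.asqrt_energy(template, deformed) == pytest.approx(
            asqrt_sum / len(hexes), rel=1e-10)


class TestSurfaceRegularizers:
    def test_planar_patch_zero_normal_energy(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        tris = np.array([[0, 1, 2], [1, 3, 2]])
        assert normal_consistency(verts, tris) == pytest.approx(0.0)

    def test_right_angle_fold(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 0, 1]], float)
        tris = np.array([[0, 1, 2], [1, 0, 3]])
        assert normal_consistency(verts, tris) == pytest.approx(1.0)

    def test_normal_matches_pairwise_loop_oracle(self, template):
        tris = template.component("lv").elements
        verts = template.nodes
        pairs = triangle_adjacency(tris)
        total = 0.0
        for f, g in pairs:
            nf = np.cross(verts[tris[f, 1]] - verts[tris[f, 0]],
                          verts[tris[f, 2]] - verts[tris[f, 0]])
            ng = np.cross(verts[tris[g, 1]] - verts[tris[g, 0]],
                          verts[tris[g, 2]] - verts[tris[g, 0]])
            total += 1 - nf @ ng / np.linalg.norm(nf) / np.linalg.norm(ng)
        assert normal_consistency(verts, tris) == pytest.approx(
            total / len(pairs), rel=1e-12)

    def test_zero_area_face_rejected(self):
        verts = np.zeros((3, 3))
        with pytest.raises(ValueError):
            normal_consistency(verts, np.array([[0, 1, 2]]))

    def test_laplacian_interior_grid_vertex_zero(self):
        # a vertex at its neighbours' centroid contributes nothing
        verts = np.array([[0, 0, 0], [1, 0, 0], [-1, 0, 0],
                          [0, 1, 0], [0, -1, 0]], float)
        edges = np.array([[0, 1], [0, 2], [0, 3], [0, 4]])
        val, grad = laplacian_smoothness_grad(verts, edges)
        # center vertex residual zero; leaves each have residual |v_i - v_0|
        assert grad is not None
        center_only = laplacian_smoothness(verts, edges)
        assert center_only == pytest.approx(4.0 / 5.0)  # leaves at dist 1

    def test_laplacian_displaced_vertex(self):
        h = 0.37
        verts = np.array([[0, 0, h], [1, 0, 0], [-1, 0, 0],
                          [0, 1, 0], [0, -1, 0]], float)
        edges = np.array([[0, 1], [0, 2], [0, 3], [0, 4]])
        # center contribution h^2; each leaf sees the center at height h
        expect = (h**2 + 4 * (1 + h**2)) / 5.0
        assert laplacian_smoothness(verts, edges) == pytest.approx(expect)

    def test_laplacian_matches_vertex_loop_oracle(self, template, rng):
        edges = template.component_edges("lv")
        verts = template.nodes + rng.normal(0, 0.1, template.nodes.shape)
        used = np.unique(edges)
        nbrs = {int(v): [] for v in used}
        for a, b in edges:
            nbrs[int(a)].append(int(b))
            nbrs[int(b)].append(int(a))
        total = sum(np.sum((verts[v] - np.mean(verts[nbrs[v]], axis=0)) ** 2)
                    for v in used)
        assert laplacian_smoothness(verts, edges) == pytest.approx(
            total / len(used), rel=1e-10)

    def test_edge_identity_and_scale_invariance(self, template):
        edges = template.component_edges("lv")
        assert edge_length_correspondence(template.nodes, template.nodes,
                                          edges) == 0.0
        assert edge_length_correspondence(
            template.nodes, template.nodes * 2.7, edges) == pytest.approx(
                0.0, abs=1e-24)

    def test_edge_hand_case_two_edges(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0]], float)
        deformed = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]], float)
        edges = np.array([[0, 1], [0, 2]])
        # before: ratios 1/2, 1; after: ratios 1, 1
        expect = ((1 - 0.5) ** 2 + 0.0) / 2
        assert edge_length_correspondence(ref, deformed,
                                          edges) == pytest.approx(expect)


class TestTotalLoss:
    def test_zero_at_reference_with_self_targets(self, template):
        targets = {n: template.nodes[template.component_nodes(n)]
                   for n in template.component_names}
        total, breakdown, _ = total_mesh_loss(template, template, targets)
        assert total == pytest.approx(0.0, abs=1e-12)
        for term in breakdown.values():
            assert term == pytest.approx(0.0, abs=1e-12)

    def test_chamfer_only_reduction(self, template, rng):
        targets = {n: vm.sample_component_surface(template, n, 400)
                   for n in template.component_names}
        w = LossWeights(lambdas=(0, 0, 0, 0, 0))
        total, breakdown, _ = total_mesh_loss(template, template, targets, w)
        chamfers = [chamfer_loss(template.nodes[template.component_nodes(n)],
                                 targets[n])
                    for n in template.component_names]
        assert total == pytest.approx(np.mean(chamfers), rel=1e-12)

    def test_equals_manual_weighted_term_sum_and_additivity(self, template,
                                                            rng):
        deformed = template.with_nodes(
            template.nodes + rng.normal(0, 0.3, template.nodes.shape))
        targets = {n: vm.sample_component_surface(template, n, 400)
                   for n in template.component_names}
        w = LossWeights()
        total, br, _ = total_mesh_loss(template, deformed, targets, w)
        assert total == pytest.approx(sum(br.values()), rel=1e-12)
        manual = np.mean([chamfer_loss(
            deformed.nodes[deformed.component_nodes(n)], targets[n])
            for n in template.component_names])
        manual += 1.0 * vm.arap_energy(template, deformed)
        manual += 10.0 * vm.asqrt_energy(template, deformed)
        lv_tris = deformed.component("lv").elements
        lv_edges = deformed.component_edges("lv")
        manual += 10.0 * normal_preservation_grad(
            template.nodes, deformed.nodes, lv_tris, need_grad=False)[0]
        manual += 10.0 * laplacian_preservation_grad(
            template.nodes, deformed.nodes, lv_edges, need_grad=False)[0]
        manual += 1.0 * edge_length_correspondence(template.nodes,
                                                   deformed.nodes, lv_edges)
        assert total == pytest.approx(manual, rel=1e-10)
        # doubling one weight doubles exactly that breakdown term
        w2 = LossWeights(lambdas=(2.0, 10.0, 10.0, 10.0, 1.0))
        _, br2, _ = total_mesh_loss(template, deformed, targets, w2)
        assert br2["arap"] == pytest.approx(2 * br["arap"], rel=1e-12)
        assert br2["asqrt"] == pytest.approx(br["asqrt"], rel=1e-12)

    def test_missing_component_rejected(self, template):
        with pytest.raises(ValueError):
            total_mesh_loss(template, template, {"lv": np.zeros((3, 3))})


class TestDice:
    def _maps(self, grids):
        return vm.LabelMaps(dict(zip(vm.COMPONENT_NAMES, grids)), np.eye(4))

    def test_perfect_match_zero_loss(self, rng):
        grids = [(rng.random((6, 6, 6)) > 0.5).astype(float)
                 for _ in range(5)]
        lm = self._maps(grids)
        assert dice_loss(lm, lm) == pytest.approx(0.0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4))
        a[:2] = 1
        b = np.zeros((4, 4, 4))
        b[2:] = 1
        la = self._maps([a] * 5)
        lb = self._maps([b] * 5)
        assert dice_loss(la, lb) == pytest.approx(5.0)

    def test_half_overlap_counting_oracle(self):
        a = np.zeros((4, 4, 4))
        a[:2] = 1.0  # 32 voxels
        b = np.zeros((4, 4, 4))
        b[1:3] = 1.0  # 32 voxels, 16 shared
        la = self._maps([a] * 5)
        lb = self._maps([b] * 5)
        # DSC = 2*16/(32+32) = 0.5 per component
        assert dice_loss(la, lb, alpha=(1.0,) * 5) == pytest.approx(2.5)

    def test_both_empty_defined_as_match(self):
        assert soft_dice(np.zeros((3, 3, 3)), np.zeros((3, 3, 3))) == 1.0

    def test_weights_applied(self):
        a = np.ones((2, 2, 2))
        b = np.zeros((2, 2, 2))
        la = self._maps([a] * 5)
        lb = self._maps([b] * 5)
        assert dice_loss(la, lb, alpha=(5, 1, 1, 1, 1)) == pytest.approx(9.0)


@pytest.mark.parametrize("name", ["arap", "asqrt", "normal", "laplacian",
                                  "normal_rel", "laplacian_rel",
                                  "edge", "chamfer"])
def test_analytic_gradients_match_finite_differences(template, name):
    """Every energy's hand-derived gradient agrees with central differences."""
    rng = np.random.default_rng(7)
    pert = template.nodes + rng.normal(0, 0.3, template.nodes.shape)
    tris = template.component("lv").elements
    edges = template.component_edges("lv")
    B = rng.normal(0, 10, (60, 3))
    funcs = {
        "arap": lambda nd: arap_energy_grad(template, template.with_nodes(nd)),
        "asqrt": lambda nd: asqrt_energy_grad(template,
                                              template.with_nodes(nd)),
        "normal": lambda nd: normal_consistency_grad(nd, tris),
        "laplacian": lambda nd: laplacian_smoothness_grad(nd, edges),
        "normal_rel": lambda nd: normal_preservation_grad(template.nodes,
                                                          nd, tris),
        "laplacian_rel": lambda nd: laplacian_preservation_grad(
            template.nodes, nd, edges),
        "edge": lambda nd: edge_length_correspondence_grad(template.nodes,
                                                           nd, edges),
        "chamfer": lambda nd: chamfer_loss_grad(nd[:80], B),
    }
    fun = funcs[name]
    _, grad = fun(pert)
    idx = rng.choice(len(pert) if name != "chamfer" else 80, 5, replace=False)
    eps = 1e-6
    for i in idx:
        for a in range(3):
            p, m = pert.copy(), pert.copy()
            p[i, a] += eps
            m[i, a] -= eps
            fd = (fun(p)[0] - fun(m)[0]) / (2 * eps)
            assert grad[i, a] == pytest.approx(fd, rel=1e-4, abs=1e-7)
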