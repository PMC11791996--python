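"""Mesh- and segmentation-based loss terms for template-deformation fitting.

The fitting objective combines per-component chamfer distance for surface
accuracy with solid-element distortion energies (isotropic ARAP and the
anisotropic "ASqrt" square-root St. Venant-Kirchhoff stretch penalty along
each element's thickness direction) and surface regularizers (normal
consistency, uniform Laplacian smoothness, edge-length-ratio correspondence).
Segmentation-driven registration uses a component-weighted soft Dice loss.

Every term is a plain scalar function of node positions with a paired
analytic gradient, so the whole objective can be minimized with first-order
optimizers without an autodiff framework.  The gradient conventions:

* ARAP uses d||F - R(F)||^2/dF = 2 (F - R): the polar-factor term drops out
  exactly because tr(S R^T dR) = 0 for symmetric S and R^T dR antisymmetric.
* The edge-ratio term treats the max edge length as locally constant
  (a subgradient; exact away from ties of the argmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .images import LabelMaps
from .mesh import MultiComponentMesh


@dataclass
class LossWeights:
    """Weights of the combined objective: lambda_1..5 multiply ARAP, ASqrt,
    normal consistency, Laplacian and edge correspondence; ``alpha`` weights
    the per-component Dice terms of segmentation-driven registration."""

    lambdas: tuple[float, float, float, float, float] = (1.0, 10.0, 10.0, 10.0, 1.0)
    alpha: tuple[float, float, float, float, float] = (5.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.lambdas) or any(a < 0 for a in self.alpha):
            raise ValueError("loss weights must be nonnegative")


# ----------------------------------------------------------------------
# chamfer
# ----------------------------------------------------------------------

def chamfer_loss(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric mean of squared nearest-neighbour distances (both directions)."""
    val, _ = chamfer_loss_grad(A, B, need_grad=False)
    return val


def chamfer_loss_grad(A: np.ndarray, B: np.ndarray, need_grad: bool = True,
                      B_normals: np.ndarray | None = None,
                      ) -> tuple[float, np.ndarray | None]:
    """Chamfer value and gradient with respect to the points of A.

    With ``B_normals`` the A->B residual is projected onto the target
    normal (point-to-plane): the value and gradient then ignore tangential
    offsets against the discrete target sampling, which otherwise lock
    nodes onto individual sample points during optimization.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("chamfer requires nonempty point sets")
    tree_b = cKDTree(B)
    d_ab, j_ab = tree_b.query(A)
    tree_a = cKDTree(A)
    d_ba, j_ba = tree_a.query(B)
    if B_normals is None:
        val = float(np.mean(d_ab**2) + np.mean(d_ba**2))
        if not need_grad:
            return val, None
        grad = 2.0 / len(A) * (A - B[j_ab])
    else:
        n = B_normals[j_ab]
        resid = np.einsum("ij,ij->i", A - B[j_ab], n)
        val = float(np.mean(resid**2) + np.mean(d_ba**2))
        if not need_grad:
            return val, None
        grad = 2.0 / len(A) * resid[:, None] * n
    np.add.at(grad, j_ba, 2.0 / len(B) * (A[j_ba] - B))
    return val, grad


# ----------------------------------------------------------------------
# solid distortion energies
# ----------------------------------------------------------------------

def _centered_corners(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    c = nodes[hexes]  # (E, 8, 3)
    return c - c.mean(axis=1, keepdims=True)


def deformation_gradient(ref_nodes: np.ndarray, def_nodes: np.ndarray,
                         hexes: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-element deformation gradient F and rotational polar factor R.

    F is the least-squares linear map carrying the centroid-referenced
    reference corner vectors onto the deformed ones:
    F = (sum x X^T)(sum X X^T)^{-1}.  R is the special-orthogonal polar
    factor of F (SVD with reflection correction).

    Returns (F, R, Xc, Binv); the last two are cached for gradient chains.
    """
    Xc = _centered_corners(ref_nodes, hexes)
    xc = _centered_corners(def_nodes, hexes)
    B = np.einsum("eci,ecj->eij", Xc, Xc)
    if np.any(np.abs(np.linalg.det(B)) < 1e-12):
        raise ValueError("degenerate reference element (rank < 3 edge span)")
    Binv = np.linalg.inv(B)
    A = np.einsum("eci,ecj->eij", xc, Xc)
    F = A @ Binv
    U, _, Vt = np.linalg.svd(F)
    det = np.linalg.det(U @ Vt)
    U = U.copy()
    U[:, :, 2] *= det[:, None]
    R = U @ Vt
    return F, R, Xc, Binv


def _scatter_element_grad(n_nodes: int, hexes: np.ndarray,
                          G: np.ndarray, Xc: np.ndarray,
                          Binv: np.ndarray) -> np.ndarray:
    """Chain dE/dF (= G) back to the deformed nodes through F = A B^{-1}."""
    # dE/dx_c = G B^{-1} X_c ; remove the centroid component, scatter-add.
    per_corner = np.einsum("eij,ejk,eck->eci", G, Binv, Xc)
    per_corner -= per_corner.mean(axis=1, keepdims=True)
    grad = np.zeros((n_nodes, 3))
    np.add.at(grad, hexes.ravel(), per_corner.reshape(-1, 3))
    return grad


def arap_energy(mesh_ref: MultiComponentMesh, mesh_def: MultiComponentMesh) -> float:
    val, _ = arap_energy_grad(mesh_ref, mesh_def, need_grad=False)
    return val


def arap_energy_grad(mesh_ref: MultiComponentMesh, mesh_def: MultiComponentMesh,
                     need_grad: bool = True) -> tuple[float, np.ndarray | None]:
    """As-rigid-as-possible energy: mean over solid elements of ||F - R||_F^2."""
    hexes = mesh_ref.all_hexes()
    if len(hexes) == 0:
        raise ValueError("no hexahedral components present")
    F, R, Xc, Binv = deformation_gradient(mesh_ref.nodes, mesh_def.nodes, hexes)
    D = F - R
    val = float(np.einsum("eij,eij->", D, D) / len(hexes))
    if not need_grad:
        return val, None
    G = 2.0 * D / len(hexes)
    return val, _scatter_element_grad(len(mesh_def.nodes), hexes, G, Xc, Binv)


def asqrt_energy(mesh_ref: MultiComponentMesh, mesh_def: MultiComponentMesh) -> float:
    val, _ = asqrt_energy_grad(mesh_ref, mesh_def, need_grad=False)
    return val


def asqrt_energy_grad(mesh_ref: MultiComponentMesh, mesh_def: MultiComponentMesh,
                      need_grad: bool = True) -> tuple[float, np.ndarray | None]:
    """Anisotropic stretch penalty: mean of (||F d|| - 1)^2 over solid
    elements, d being each element's unit thickness direction."""
    hexes = mesh_ref.all_hexes()
    if len(hexes) == 0:
        raise ValueError("no hexahedral components present")
    d = mesh_ref.all_anisotropy()
    norms = np.linalg.norm(d, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("anisotropy directions must be unit vectors")
    F, _, Xc, Binv = deformation_gradient(mesh_ref.nodes, mesh_def.nodes, hexes)
    w = np.einsum("eij,ej->ei", F, d)
    s = np.linalg.norm(w, axis=1)
    val = float(np.mean((s - 1.0) ** 2))
    if not need_grad:
        return val, None
    coef = 2.0 * (s - 1.0) / np.maximum(s, 1e-12) / len(hexes)
    G = coef[:, None, None] * w[:, :, None] * d[:, None, :]
    return val, _scatter_element_grad(len(mesh_def.nodes), hexes, G, Xc, Binv)


# ----------------------------------------------------------------------
# surface regularizers
# ----------------------------------------------------------------------

def triangle_adjacency(tris: np.ndarray) -> np.ndarray:
    """Pairs of triangle indices sharing an edge."""
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    owner = np.tile(np.arange(len(tris)), 3)
    key = np.sort(edges, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key, owner = key[order], owner[order]
    same = np.all(key[1:] == key[:-1], axis=1)
    return np.column_stack([owner[:-1][same], owner[1:][same]])


def _face_normals(verts: np.ndarray, tris: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, b, c = (verts[tris[:, i]] for i in range(3))
    cr = np.cross(b - a, c - a)
    nrm = np.linalg.norm(cr, axis=1)
    if np.any(nrm < 1e-14):
        raise ValueError("zero-area face")
    return cr, nrm, cr / nrm[:, None]


def normal_consistency(verts: np.ndarray, tris: np.ndarray) -> float:
    val, _ = normal_consistency_grad(verts, tris, need_grad=False)
    return val


def normal_consistency_grad(verts: np.ndarray, tris: np.ndarray,
                            need_grad: bool = True,
                            pairs: np.ndarray | None = None,
                            ) -> tuple[float, np.ndarray | None]:
    """Mean over adjacent face pairs of 1 - cos(angle between unit normals)."""
    if pairs is None:
        pairs = triangle_adjacency(tris)
    cr, nrm, n = _face_normals(verts, tris)
    cos = np.einsum("pi,pi->p", n[pairs[:, 0]], n[pairs[:, 1]])
    val = float(np.mean(1.0 - cos))
    if not need_grad:
        return val, None
    # d(1 - n_f . n_g)/d cr_f = -(I - n_f n_f^T) n_g / |cr_f|
    g_face = np.zeros_like(cr)
    for s in (0, 1):
        f, g = pairs[:, s], pairs[:, 1 - s]
        proj = n[g] - cos[:, None] * n[f]
        np.add.at(g_face, f, -proj / nrm[f][:, None] / len(pairs))
    # distribute d cr = d(b - a) x (c - a) + (b - a) x d(c - a)
    a, b, c = (verts[tris[:, i]] for i in range(3))
    grad = np.zeros_like(verts)
    gb = np.cross(c - a, g_face)   # d/d(b - a)
    gc = np.cross(g_face, b - a)   # d/d(c - a)
    np.add.at(grad, tris[:, 1], gb)
    np.add.at(grad, tris[:, 2], gc)
    np.add.at(grad, tris[:, 0], -(gb + gc))
    return val, grad


def normal_preservation_grad(ref_verts: np.ndarray, def_verts: np.ndarray,
                             tris: np.ndarray, need_grad: bool = True,
                             pairs: np.ndarray | None = None,
                             ) -> tuple[float, np.ndarray | None]:
    """Mean squared change of adjacent-face normal agreement between the
    reference and deformed surface: mean over pairs of
    (cos theta_def - cos theta_ref)^2.

    The deformation-regularizing counterpart of the normal-consistency
    energy: zero at the identity for any (curved) reference, and for a flat
    reference it penalizes exactly the folds the plain energy measures.
    """
    if pairs is None:
        pairs = triangle_adjacency(tris)
    _, _, n_ref = _face_normals(ref_verts, tris)
    cr, nrm, n = _face_normals(def_verts, tris)
    cos_ref = np.einsum("pi,pi->p", n_ref[pairs[:, 0]], n_ref[pairs[:, 1]])
    cos_def = np.einsum("pi,pi->p", n[pairs[:, 0]], n[pairs[:, 1]])
    diff = cos_def - cos_ref
    val = float(np.mean(diff**2))
    if not need_grad:
        return val, None
    g_face = np.zeros_like(cr)
    for s in (0, 1):
        f, g = pairs[:, s], pairs[:, 1 - s]
        proj = n[g] - cos_def[:, None] * n[f]
        np.add.at(g_face, f,
                  (2.0 * diff / len(pairs))[:, None] * proj / nrm[f][:, None])
    a, b, c = (def_verts[tris[:, i]] for i in range(3))
    grad = np.zeros_like(def_verts)
    gb = np.cross(c - a, g_face)
    gc = np.cross(g_face, b - a)
    np.add.at(grad, tris[:, 1], gb)
    np.add.at(grad, tris[:, 2], gc)
    np.add.at(grad, tris[:, 0], -(gb + gc))
    return val, grad


def vertex_adjacency(edges: np.ndarray, n_verts: int):
    """Sparse uniform-Laplacian operator L = I - D^{-1} A from an edge list."""
    from scipy.sparse import coo_matrix, eye, diags
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    A = coo_matrix((np.ones(len(i)), (i, j)), shape=(n_verts, n_verts)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("isolated vertex in surface mesh")
    return (eye(n_verts) - diags(1.0 / deg) @ A).tocsr()


def laplacian_smoothness(verts: np.ndarray, edges: np.ndarray) -> float:
    val, _ = laplacian_smoothness_grad(verts, edges, need_grad=False)
    return val


def laplacian_smoothness_grad(verts: np.ndarray, edges: np.ndarray,
                              need_grad: bool = True, L=None,
                              ) -> tuple[float, np.ndarray | None]:
    """Mean over surface vertices of ||v_i - mean(neighbours)||^2.

    ``verts`` may be a full node array; only vertices referenced by
    ``edges`` enter the mean (and receive gradient).
    """
    used = np.unique(edges)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub_edges = remap[edges]
    sub = verts[used]
    if L is None:
        L = vertex_adjacency(sub_edges, len(used))
    r = L @ sub
    val = float(np.sum(r**2) / len(used))
    if not need_grad:
        return val, None
    grad = np.zeros_like(verts)
    grad[used] = 2.0 / len(used) * (L.T @ r)
    return val, grad


def laplacian_preservation_grad(ref_verts: np.ndarray, def_verts: np.ndarray,
                                edges: np.ndarray, need_grad: bool = True,
                                ) -> tuple[float, np.ndarray | None]:
    """Mean squared change of the uniform Laplacian coordinates
    delta_i = v_i - mean(neighbours) between reference and deformed mesh.

    This is the deformation-regularizing form of the uniform Laplacian
    smoothness term: it vanishes at the identity deformation for any
    reference (a curved template is not penalized for its own curvature)
    and reduces to the plain smoothness energy when the reference has zero
    Laplacian coordinates.
    """
    used = np.unique(edges)
    remap = -np.ones(len(ref_verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub_edges = remap[edges]
    L = vertex_adjacency(sub_edges, len(used))
    r = L @ def_verts[used] - L @ ref_verts[used]
    val = float(np.sum(r**2) / len(used))
    if not need_grad:
        return val, None
    grad = np.zeros_like(def_verts)
    grad[used] = 2.0 / len(used) * (L.T @ r)
    return val, grad


def edge_length_correspondence(ref_verts: np.ndarray, def_verts: np.ndarray,
                               edges: np.ndarray) -> float:
    val, _ = edge_length_correspondence_grad(ref_verts, def_verts, edges,
                                             need_grad=False)
    return val


def edge_length_correspondence_grad(ref_verts: np.ndarray,
                                    def_verts: np.ndarray,
                                    edges: np.ndarray,
                                    need_grad: bool = True,
                                    ref_lengths: np.ndarray | None = None,
                                    ) -> tuple[float, np.ndarray | None]:
    """Mean squared difference of max-normalized edge-length ratios before
    and after deformation (scale-invariant shape preservation).

    ``ref_lengths`` overrides the per-edge rest lengths (used when part of
    the reference configuration is synthetic, e.g. stitching bands)."""
    if len(edges) == 0:
        raise ValueError("empty edge set")
    d_def = def_verts[edges[:, 0]] - def_verts[edges[:, 1]]
    if ref_lengths is None:
        d_ref = ref_verts[edges[:, 0]] - ref_verts[edges[:, 1]]
        l_ref = np.linalg.norm(d_ref, axis=1)
    else:
        l_ref = np.asarray(ref_lengths, dtype=float)
    l_def = np.linalg.norm(d_def, axis=1)
    m_ref, m_def = l_ref.max(), l_def.max()
    if m_ref < 1e-14 or m_def < 1e-14:
        raise ValueError("zero maximum edge length")
    r = l_def / m_def - l_ref / m_ref
    val = float(np.mean(r**2))
    if not need_grad:
        return val, None
    coef = 2.0 * r / len(edges) / m_def / np.maximum(l_def, 1e-14)
    g_edge = coef[:, None] * d_def
    grad = np.zeros_like(def_verts)
    np.add.at(grad, edges[:, 0], g_edge)
    np.add.at(grad, edges[:, 1], -g_edge)
    return val, grad


# ----------------------------------------------------------------------
# combined objective
# ----------------------------------------------------------------------

def total_mesh_loss(mesh_ref: MultiComponentMesh, mesh_def: MultiComponentMesh,
                    targets: dict[str, np.ndarray],
                    weights: LossWeights | None = None,
                    need_grad: bool = False,
                    ) -> tuple[float, dict[str, float], np.ndarray | None]:
    """Combined surface+solid fitting objective.

    mean-over-components chamfer + l1*ARAP + l2*ASqrt (solids)
    + l3*normal + l4*Laplacian + l5*edge (LV surface shell).

    The surface smoothness terms enter in their deformation-regularizing
    (preservation) forms — squared change of adjacent-face normal agreement
    and of uniform Laplacian coordinates relative to the reference — so the
    whole objective is exactly zero at the identity deformation with
    self-targets, as a template-deformation objective must be.  Target
    entries may be point arrays or (points, normals) tuples; with normals
    the mesh->target chamfer residual is point-to-plane.

    Returns (total, per-term breakdown, gradient w.r.t. deformed nodes).
    """
    weights = weights or LossWeights()
    names = mesh_def.component_names
    missing = [n for n in names if n not in targets]
    if missing:
        raise ValueError(f"missing target point sets for {missing}")
    l1, l2, l3, l4, l5 = weights.lambdas
    grad = np.zeros_like(mesh_def.nodes) if need_grad else None
    breakdown: dict[str, float] = {}

    ch_total = 0.0
    for name in names:
        idx = mesh_def.component_nodes(name)
        tgt = targets[name]
        pts, nrm = tgt if isinstance(tgt, tuple) else (tgt, None)
        val, g = chamfer_loss_grad(mesh_def.nodes[idx], pts,
                                   need_grad=need_grad, B_normals=nrm)
        ch_total += val / len(names)
        if need_grad:
            np.add.at(grad, idx, g / len(names))
    breakdown["chamfer"] = ch_total

    val, g = arap_energy_grad(mesh_ref, mesh_def, need_grad=need_grad)
    breakdown["arap"] = l1 * val
    if need_grad:
        grad += l1 * g
    val, g = asqrt_energy_grad(mesh_ref, mesh_def, need_grad=need_grad)
    breakdown["asqrt"] = l2 * val
    if need_grad:
        grad += l2 * g

    lv_tris = mesh_def.component("lv").elements
    lv_edges = mesh_def.component_edges("lv")
    val, g = normal_preservation_grad(mesh_ref.nodes, mesh_def.nodes,
                                      lv_tris, need_grad=need_grad)
    breakdown["normal"] = l3 * val
    if need_grad:
        grad += l3 * g
    val, g = laplacian_preservation_grad(mesh_ref.nodes, mesh_def.nodes,
                                         lv_edges, need_grad=need_grad)
    breakdown["laplacian"] = l4 * val
    if need_grad:
        grad += l4 * g
    val, g = edge_length_correspondence_grad(mesh_ref.nodes, mesh_def.nodes,
                                             lv_edges, need_grad=need_grad)
    breakdown["edge"] = l5 * val
    if need_grad:
        grad += l5 * g

    total = float(sum(breakdown.values()))
    return total, breakdown, grad


# ----------------------------------------------------------------------
# Dice
# ----------------------------------------------------------------------

def soft_dice(p: np.ndarray, g: np.ndarray) -> float:
    """Soft Dice similarity 2 sum(pg) / (sum p + sum g); 1 if both empty."""
    denom = float(p.sum() + g.sum())
    if denom == 0.0:
        return 1.0
    return float(2.0 * np.sum(p * g) / denom)


def dice_loss(pred: LabelMaps, truth: LabelMaps,
              alpha: tuple[float, ...] = (1.0,) * 5) -> float:
    """Weighted sum over components of (1 - Dice similarity)."""
    if pred.shape != truth.shape:
        raise ValueError("label maps must share a lattice")
    total = 0.0
    for a, name in zip(alpha, pred.components):
        total += a * (1.0 - soft_dice(pred.components[name],
                                      truth.components[name]))
    return float(total)


def soft_dice_grad(p: np.ndarray, g: np.ndarray) -> tuple[float, np.ndarray]:
    """Dice similarity and its gradient w.r.t. the soft prediction p."""
    sp, sg = float(p.sum()), float(g.sum())
    denom = sp + sg
    if denom == 0.0:
        return 1.0, np.zeros_like(p)
    inter = float(np.sum(p * g))
    dsc = 2.0 * inter / denom
    grad = (2.0 * g * denom - 2.0 * inter) / denom**2
    return dsc, grad
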