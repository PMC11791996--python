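"""Template fitting pipelines.

Two routes reconstruct a patient mesh by deforming the fixed-topology
template:

* surface-target energy minimization: the combined chamfer + distortion +
  surface-regularizer objective is minimized per case over a similarity
  transform followed by a diffeomorphic b-spline velocity field (the same
  objective a learned predictor would amortize; a per-case first-order
  optimizer exercises it directly, and an externally supplied displacement
  predictor can be hooked in via ``init_velocity``);
* segmentation-driven two-stage registration: a similarity stage minimizes
  a component-weighted soft Dice loss (LV weighted 5x), then the non-rigid
  stage minimizes uniform-weight Dice + bending-energy regularization +
  edge-length correspondence over the velocity controls.

The template is coupled to the segmentation lattice through a smooth
rasterization: each component is covered by deterministic volume-weighted
sample points that are splatted trilinearly into the lattice, giving a soft
occupancy in [0, 1] whose exact adjoint provides analytic gradients with
respect to node positions.

Gradients are pulled back from the integrated displacement to the velocity
controls with the first-order approximation d exp(v)/dv ~ identity
(log-demons practice); the loss itself is always evaluated through the full
scaling-and-squaring integration, so the positive-Jacobian guarantee of the
output deformation is never weakened.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .deformation import (BSplineDiffeo, SimilarityTransform, bending_energy,
                          bending_energy_gradient, coarse_view,
                          densify_velocity, integrate_velocity,
                          jacobian_determinant, prefilter_displacement,
                          pullback_to_controls, sample_displacement)
from .energies import (LossWeights, soft_dice_grad,
                       edge_length_correspondence_grad, total_mesh_loss)
from .images import (COMPONENT_NAMES, CalcificationSegmentation, LabelMaps,
                     VoxelImage, interpolate_at_points)
from .mesh import MultiComponentMesh, sample_hexes, sample_triangles


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationResult:
    sim: SimilarityTransform
    diffeo: BSplineDiffeo | None
    fitted_mesh: MultiComponentMesh
    loss_trace: list[float]
    breakdown: dict[str, float] = field(default_factory=dict)
    converged: bool = True


class Adam:
    """First-order moment-adaptive optimizer (per parameter group)."""

    def __init__(self, lr: float, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = self.v = None
        self.t = 0

    def step(self, param: np.ndarray, grad: np.ndarray,
             lr_scale: float = 1.0) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(param)
            self.v = np.zeros_like(param)
        b1, b2 = self.betas
        self.t += 1
        self.m = b1 * self.m + (1 - b1) * grad
        self.v = b2 * self.v + (1 - b2) * grad**2
        mhat = self.m / (1 - b1**self.t)
        vhat = self.v / (1 - b2**self.t)
        return param - self.lr * lr_scale * mhat / (np.sqrt(vhat) + self.eps)


def _cosine_decay(it: int, total: int, floor: float = 0.02) -> float:
    return floor + (1 - floor) * 0.5 * (1 + np.cos(np.pi * it / max(total, 1)))


# ----------------------------------------------------------------------
# smooth rasterization
# ----------------------------------------------------------------------

def component_samples(mesh: MultiComponentMesh, voxel_spacing: float,
                      points_per_voxel: float = 4.0,
                      ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Deterministic volume-weighted sample points per component.

    Solid components are sampled inside their hexahedra; the LV surface
    shell is sampled on its triangles with a nominal one-voxel thickness so
    it rasterizes to a one-voxel occupancy shell.
    """
    vv = voxel_spacing**3
    out = {}
    for blk in mesh.components:
        if blk.kind == "hexahedron":
            pts, wts = sample_hexes(mesh.nodes, blk.elements,
                                    per_volume=points_per_voxel / vv)
        else:
            pts, wts = sample_triangles(
                mesh.nodes, blk.elements,
                per_area=points_per_voxel / voxel_spacing**2)
            wts = wts * voxel_spacing  # area -> nominal shell volume
        out[blk.name] = (pts, wts)
    return out


def splat_density(points: np.ndarray, volumes: np.ndarray,
                  shape: tuple[int, int, int], affine: np.ndarray,
                  mode: str = "linear") -> np.ndarray:
    """Deposition of per-point volumes, normalized by voxel volume: the
    result approximates occupancy density (~1 inside).

    ``linear`` splats trilinearly (differentiable, used during fitting);
    ``nearest`` deposits into the containing voxel, giving sharp unbiased
    coverage fractions (used for ground-truth rasterization).
    """
    inv = np.linalg.inv(affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    voxel_vol = abs(np.linalg.det(affine[:3, :3]))
    grid = np.zeros(shape)
    flat = grid.ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    n_flat = flat.size
    if mode == "nearest":
        idx = np.round(vox).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        flat += np.bincount((idx[ok] * strides).sum(axis=1),
                            volumes[ok] / voxel_vol, minlength=n_flat)
        return grid
    i0 = np.floor(vox).astype(int)
    f = vox - i0
    for bits in range(8):
        b = np.array([(bits >> 2) & 1, (bits >> 1) & 1, bits & 1])
        idx = i0 + b
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        w = np.prod(np.where(b, f, 1 - f), axis=1)
        flat += np.bincount((idx[ok] * strides).sum(axis=1),
                            w[ok] * volumes[ok] / voxel_vol,
                            minlength=n_flat)
    return grid


def splat_density_backward(points: np.ndarray, volumes: np.ndarray,
                           grid_grad: np.ndarray, affine: np.ndarray,
                           ) -> np.ndarray:
    """Gradient of any scalar of the splatted density w.r.t. the points."""
    inv = np.linalg.inv(affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    voxel_vol = abs(np.linalg.det(affine[:3, :3]))
    shape = grid_grad.shape
    i0 = np.floor(vox).astype(int)
    f = vox - i0
    g_vox = np.zeros_like(points)
    flat = grid_grad.ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    for bits in range(8):
        b = np.array([(bits >> 2) & 1, (bits >> 1) & 1, bits & 1])
        idx = i0 + b
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        g = np.zeros(len(points))
        g[ok] = flat[(idx[ok] * strides).sum(axis=1)]
        wx = np.where(b, f, 1 - f)
        sx = np.where(b, 1.0, -1.0)
        for a in range(3):
            others = wx[:, [x for x in range(3) if x != a]].prod(axis=1)
            g_vox[:, a] += g * sx[a] * others
    g_vox *= (volumes / voxel_vol)[:, None]
    return g_vox @ inv[:3, :3]  # chain through vox = inv A p


def _splat_vector_adjoint(points: np.ndarray, grads: np.ndarray,
                          shape: tuple[int, int, int], affine: np.ndarray,
                          ) -> np.ndarray:
    """Adjoint of trilinear vector-field sampling: scatter per-point
    gradient vectors back onto the lattice.  Returns (3, *shape) in the
    field's units."""
    inv = np.linalg.inv(affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    out = np.zeros((3,) + tuple(shape))
    i0 = np.floor(vox).astype(int)
    i0 = np.clip(i0, 0, np.array(shape) - 2)  # 'nearest' edge handling
    f = np.clip(vox - i0, 0.0, 1.0)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    n_flat = int(np.prod(shape))
    for bits in range(8):
        b = np.array([(bits >> 2) & 1, (bits >> 1) & 1, bits & 1])
        lin = ((i0 + b) * strides).sum(axis=1)
        w = np.prod(np.where(b, f, 1 - f), axis=1)
        for c in range(3):
            out[c] += np.bincount(lin, w * grads[:, c],
                                  minlength=n_flat).reshape(shape)
    return out


def _splat_scalar_adjoint(points: np.ndarray, vals: np.ndarray,
                          shape: tuple[int, int, int], affine: np.ndarray,
                          ) -> np.ndarray:
    """Adjoint of trilinear scalar sampling: scatter per-point scalars."""
    inv = np.linalg.inv(affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    i0 = np.clip(np.floor(vox).astype(int), 0, np.array(shape) - 2)
    f = np.clip(vox - i0, 0.0, 1.0)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    out = np.zeros(int(np.prod(shape)))
    for bits in range(8):
        b = np.array([(bits >> 2) & 1, (bits >> 1) & 1, bits & 1])
        lin = ((i0 + b) * strides).sum(axis=1)
        w = np.prod(np.where(b, f, 1 - f), axis=1)
        out += np.bincount(lin, w * vals, minlength=out.size)
    return out.reshape(shape)


def _sample_scalar(grid: np.ndarray, affine: np.ndarray,
                   points: np.ndarray) -> np.ndarray:
    from scipy.ndimage import map_coordinates
    inv = np.linalg.inv(affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    return map_coordinates(grid, vox.T, order=1, mode="nearest")


def _dice_forward_backward(warped: dict[str, tuple[np.ndarray, np.ndarray]],
                           truth: LabelMaps, alpha: tuple[float, ...],
                           blur_sigma_vox: float = 0.0,
                           ) -> tuple[float, dict[str, np.ndarray],
                                      dict[str, np.ndarray]]:
    """Soft Dice loss of splatted occupancies vs. the target labels, with
    gradients w.r.t. the warped sample points and the per-point volumes.

    ``blur_sigma_vox`` Gaussian-blurs both fields before the overlap is
    measured — a graduated-smoothing device that extends the capture range
    for thin structures early in the optimization (the blur is linear and
    self-adjoint, so the gradient is exact).
    """
    from scipy.ndimage import gaussian_filter
    loss = 0.0
    point_grads = {}
    weight_grads = {}
    affine = truth.affine
    shape = truth.shape
    for a, name in zip(alpha, COMPONENT_NAMES):
        pts, vols = warped[name]
        dens = splat_density(pts, vols, shape, affine)
        occ = np.minimum(dens, 1.0)
        g_ref = truth.components[name]
        if blur_sigma_vox > 0:
            occ = gaussian_filter(occ, blur_sigma_vox)
            g_ref = gaussian_filter(g_ref, blur_sigma_vox)
        dsc, g_occ = soft_dice_grad(occ, g_ref)
        loss += a * (1.0 - dsc)
        if blur_sigma_vox > 0:
            g_occ = gaussian_filter(g_occ, blur_sigma_vox)
        g_dens = np.where(dens < 1.0, -a * g_occ, 0.0)
        point_grads[name] = splat_density_backward(pts, vols, g_dens, affine)
        voxel_vol = abs(np.linalg.det(affine[:3, :3]))
        weight_grads[name] = _sample_scalar(g_dens, affine, pts) / voxel_vol
    return float(loss), point_grads, weight_grads


def rasterize_mesh(mesh: MultiComponentMesh, lattice: VoxelImage,
                   points_per_voxel: float = 64.0,
                   binarize: bool = False,
                   mode: str = "nearest") -> LabelMaps:
    """Rasterize every component onto a lattice as occupancy in [0, 1].

    Default output is soft per-voxel coverage fractions (sharp "nearest"
    deposition, volume-unbiased); ``binarize`` thresholds at 0.5.
    ``mode="linear"`` instead uses the trilinear splat convention of the
    registration forward model (so a rasterized mesh is a fixed point of
    Dice-driven fitting).
    """
    spacing = float(lattice.spacing[0])
    samples = component_samples(mesh, spacing, points_per_voxel)
    comps = {}
    for name in COMPONENT_NAMES:
        pts, vols = samples[name]
        dens = splat_density(pts, vols, lattice.shape, lattice.affine,
                             mode=mode)
        occ = np.minimum(dens, 1.0)
        comps[name] = (occ >= 0.5).astype(float) if binarize else occ
    return LabelMaps(comps, lattice.affine)


# ----------------------------------------------------------------------
# similarity stage
# ----------------------------------------------------------------------

def fit_similarity_to_labels(template: MultiComponentMesh, pred: LabelMaps,
                             alpha: tuple[float, ...] = (5.0, 1.0, 1.0, 1.0, 1.0),
                             iters: int = 500,
                             lrs: tuple[float, float, float] = (0.1, 0.1, 1.0),
                             points_per_voxel: float = 8.0,
                             tol: float = 1e-6,
                             ) -> SimilarityTransform:
    """Similarity registration of the template to predicted segmentations.

    Minimizes the component-weighted Dice loss (LV weighted 5x so the
    largest structure anchors the global pose) over anisotropic scale,
    rotation and translation with separate Adam optimizers at learning
    rates 0.1, 0.1 and 1.
    """
    union = pred.union().values
    if union.max() <= 0:
        raise RegistrationError("empty predicted segmentation")
    lat = pred.grid(COMPONENT_NAMES[0])
    spacing = float(lat.spacing[0])
    samples = component_samples(template, spacing, points_per_voxel)
    all_pts = np.concatenate([samples[n][0] for n in COMPONENT_NAMES])
    slices, start = {}, 0
    for n in COMPONENT_NAMES:
        m = len(samples[n][0])
        slices[n] = slice(start, start + m)
        start += m

    center = all_pts.mean(axis=0)
    nz = np.argwhere(union > 0)
    t0 = lat.voxel_to_world(nz.astype(float)).mean(axis=0) \
        if len(nz) else np.zeros(3)
    scale = np.ones(3)
    rot = np.zeros(3)
    trans = t0 - center

    opt_s, opt_r, opt_t = (Adam(lr) for lr in lrs)
    best = (np.inf, scale.copy(), rot.copy(), trans.copy())
    trace: list[float] = []
    for it in range(iters):
        sim = SimilarityTransform(rot, trans, scale, center)
        R = sim.rotation_matrix()
        X = all_pts - center
        warped_pts = (scale * X) @ R.T + center + trans
        # sample volumes transport with the transform's volume factor
        warped = {n: (warped_pts[slices[n]], samples[n][1] * scale.prod())
                  for n in COMPONENT_NAMES}
        loss, pgrads, _ = _dice_forward_backward(warped, pred, alpha)
        trace.append(loss)
        if loss < best[0]:
            best = (loss, scale.copy(), rot.copy(), trans.copy())
        if _stalled(trace, tol):
            break
        g = np.concatenate([pgrads[n] for n in COMPONENT_NAMES])
        g_t = g.sum(axis=0)
        g_s = (g @ R * X).sum(axis=0)
        g_r = np.empty(3)
        for k in range(3):
            eps = 1e-5
            rp, rm = rot.copy(), rot.copy()
            rp[k] += eps
            rm[k] -= eps
            dR = (SimilarityTransform(rp, trans, scale, center).rotation_matrix()
                  - SimilarityTransform(rm, trans, scale, center).rotation_matrix()
                  ) / (2 * eps)
            g_r[k] = float(np.sum(g * ((scale * X) @ dR.T)))
        lr_s = _cosine_decay(it, iters)
        scale = np.clip(opt_s.step(scale, g_s, lr_s), 0.2, 5.0)
        rot = opt_r.step(rot, g_r, lr_s)
        trans = opt_t.step(trans, g_t, lr_s)
    _, scale, rot, trans = best
    return SimilarityTransform(rot, trans, scale, center)


def _stalled(trace: list[float], tol: float, window: int = 30) -> bool:
    if len(trace) < 2 * window:
        return False
    prev = np.mean(trace[-2 * window:-window])
    cur = np.mean(trace[-window:])
    return abs(prev - cur) <= tol * max(abs(prev), 1e-12)


# ----------------------------------------------------------------------
# non-rigid, segmentation-driven
# ----------------------------------------------------------------------

def isosurface_targets(template: MultiComponentMesh, pred: LabelMaps,
                       ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-component isosurface point clouds (with normals) extracted from
    predicted occupancies, for surface-driven initialization.

    Thick solids are extracted at the 0.5 coverage level (their component
    surface is the pair of wall faces).  Shell-like components (the LV
    surface shell and sub-2-voxel leaflet slabs) rasterize to thin slabs
    whose 0.5-level isosurface is double-faced and straddles the true
    surface either way, so the level is irrelevant to first order; the
    0.5 level keeps the two faces symmetric about the midsurface, matching
    the component's own double-faced surface representation.
    """
    from skimage.measure import marching_cubes
    lat = pred.grid(COMPONENT_NAMES[0])
    targets = {}
    for n in COMPONENT_NAMES:
        g = pred.components[n]
        level = min(0.5, 0.6 * float(g.max()))
        if not g.min() < level < g.max():
            raise RegistrationError(f"component {n!r} has no isosurface")
        verts, _, vnormals, _ = marching_cubes(g, level=level)
        targets[n] = (lat.voxel_to_world(verts), vnormals)
    return targets


def _chamfer_warm_start(template: MultiComponentMesh, pred: LabelMaps,
                        init: SimilarityTransform, field: BSplineDiffeo,
                        comp: BSplineDiffeo, iters: int,
                        lr: float = 1e-2) -> None:
    """Initialize the velocity by minimizing the full surface+distortion
    objective against isosurfaces of the predicted occupancies.

    Voxelized labels carry limited sub-voxel information, so the Dice
    objective alone has shallow spurious optima around thin structures;
    fitting the isosurface point clouds first (with the distortion
    regularizers damping their quantization noise) lands the field in the
    geometry-faithful basin.  Updates ``field``/``comp`` (shared
    coefficients) in place.
    """
    targets = isosurface_targets(template, pred)
    base_nodes = init.apply(template.nodes)
    opt = Adam(lr)
    for it in range(iters):
        disp = integrate_velocity(comp)
        disp_c = prefilter_displacement(disp)
        nodes1 = base_nodes + sample_displacement(disp_c, comp.affine,
                                                  base_nodes, order=3,
                                                  prefiltered=True)
        _, _, g = total_mesh_loss(template, template.with_nodes(nodes1),
                                  targets, need_grad=True)
        dense_grad = _splat_vector_adjoint(base_nodes, g, comp.shape,
                                           comp.affine)
        ctrl_grad = pullback_to_controls(comp, dense_grad)
        field.velocity = opt.step(field.velocity, ctrl_grad,
                                  _cosine_decay(it, iters))
        comp.velocity = field.velocity


def fit_nonrigid_to_labels(template: MultiComponentMesh, pred: LabelMaps,
                           init: SimilarityTransform,
                           lambdas: tuple[float, float] = (1e-2, 1.0),
                           iters: int = 1500, lr: float = 1e-2,
                           control_spacing: int = 3,
                           integration_steps: int = 6,
                           points_per_voxel: float = 4.0,
                           tol: float = 1e-6,
                           init_velocity: np.ndarray | None = None,
                           warm_start_iters: int = 250,
                           log_jsonl: str | None = None,
                           ) -> RegistrationResult:
    """Diffeomorphic b-spline refinement against predicted segmentations.

    Objective: uniform-weight Dice loss + lambda_1 * bending energy +
    lambda_2 * edge-length correspondence, minimized over the control
    velocities (3-voxel control spacing) with Adam at learning rate 1e-2.

    The velocity is first warm-started by a chamfer fit of the template
    component surfaces to the 0.5-level isosurfaces of the predicted
    occupancies.  Voxelized labels carry little sub-voxel information, so
    the Dice objective has shallow spurious optima that reshape thin
    structures; the isosurface fit has unlimited capture range and lands in
    the geometry-faithful basin, from which the Dice descent refines.
    """
    lat = pred.grid(COMPONENT_NAMES[0])
    spacing = float(lat.spacing[0])
    field = BSplineDiffeo.zeros(pred.shape, pred.affine, control_spacing,
                                integration_steps)
    if init_velocity is not None:
        if init_velocity.shape != field.velocity.shape:
            raise ValueError("init_velocity has wrong control-grid shape")
        field.velocity = np.asarray(init_velocity, dtype=float).copy()
    samples = component_samples(template, spacing, points_per_voxel)
    base = {n: (init.apply(samples[n][0]), samples[n][1])
            for n in COMPONENT_NAMES}
    base_nodes = init.apply(template.nodes)
    edges = template.all_edges()
    l_bend, l_edge = lambdas
    comp = coarse_view(field)  # integrate/pull back at control resolution

    if warm_start_iters > 0 and init_velocity is None:
        _chamfer_warm_start(template, pred, init, field, comp,
                            warm_start_iters)

    opt = Adam(lr)
    trace: list[float] = []
    breakdown: dict[str, float] = {}
    log = open(log_jsonl, "w") if log_jsonl else None
    best_v, best_loss = field.velocity.copy(), np.inf
    try:
        for it in range(iters):
            frac = it / max(iters, 1)
            # demons-style force preconditioning: smooth the control-lattice
            # gradient early to extend capture range on thin structures,
            # annealed away so the sharp optimum is untouched; unnecessary
            # after a warm start, which already provides the capture
            precond_sigma = 0.0 if warm_start_iters > 0 else max(
                0.0, 3.0 * (1.0 - frac / 0.6))
            lr_sc = _cosine_decay(it, iters)
            disp = integrate_velocity(comp)
            disp_c = prefilter_displacement(disp)
            # volume transport: deposited sample volumes scale with the
            # local Jacobian determinant, so occupancy density is invariant
            # under the deformation (no spurious Dice gain by compression)
            jd_raw = jacobian_determinant(disp, comp.spacing)
            jd = np.clip(jd_raw, 0.2, 5.0)
            warped = {}
            for n in COMPONENT_NAMES:
                p0, w = base[n]
                p1 = p0 + sample_displacement(disp_c, comp.affine, p0,
                                              order=3, prefiltered=True)
                wj = w * _sample_scalar(jd, comp.affine, p0)
                warped[n] = (p1, wj)
            dice_val, pgrads, wgrads = _dice_forward_backward(
                warped, pred, alpha=(1.0,) * 5)
            nodes1 = base_nodes + sample_displacement(disp_c, comp.affine,
                                                      base_nodes, order=3,
                                                      prefiltered=True)
            edge_val, g_nodes = edge_length_correspondence_grad(
                base_nodes, nodes1, edges)
            phi_vox = disp / comp.spacing
            bend_val, g_bend_vox = bending_energy_gradient(phi_vox)
            total = dice_val + l_bend * bend_val + l_edge * edge_val
            trace.append(total)
            breakdown = {"dice": dice_val, "bending": l_bend * bend_val,
                         "edge": l_edge * edge_val}
            if log:
                log.write(json.dumps({"iter": it, "total": total,
                                      **breakdown}) + "\n")
            if total < best_loss:
                best_loss, best_v = total, field.velocity.copy()
            if _stalled(trace, tol):
                break
            dense_grad = l_bend * g_bend_vox / comp.spacing
            all_p0 = np.concatenate([base[n][0] for n in COMPONENT_NAMES])
            all_pg = np.concatenate([pgrads[n] for n in COMPONENT_NAMES])
            dense_grad += _splat_vector_adjoint(all_p0, all_pg, comp.shape,
                                                comp.affine)
            dense_grad += _splat_vector_adjoint(base_nodes, l_edge * g_nodes,
                                                comp.shape, comp.affine)
            # gradient through the volume transport: the divergence-form
            # adjoint of d det(I + grad u)/du.  Without it the Dice gradient
            # keeps a spurious compression force whose loss benefit the
            # transported weights have already cancelled, and the optimizer
            # drifts uphill after converging.
            beta_pts = np.concatenate([wgrads[n] * base[n][1]
                                       for n in COMPONENT_NAMES])
            beta = _splat_scalar_adjoint(all_p0, beta_pts, comp.shape,
                                         comp.affine)
            u = disp / comp.spacing
            F = np.empty(tuple(comp.shape) + (3, 3))
            for c in range(3):
                g1 = np.gradient(u[c])
                for a2 in range(3):
                    F[..., c, a2] = g1[a2]
            F += np.eye(3)
            Finv = np.linalg.inv(F)
            coefs = beta * jd * ((jd_raw > 0.2) & (jd_raw < 5.0))
            for c in range(3):
                acc = np.zeros(comp.shape)
                for a2 in range(3):
                    acc -= np.gradient(coefs * Finv[..., a2, c], axis=a2)
                dense_grad[c] += acc / comp.spacing
            ctrl_grad = pullback_to_controls(comp, dense_grad)
            if precond_sigma > 0:
                from scipy.ndimage import gaussian_filter
                for c in range(3):
                    ctrl_grad[c] = gaussian_filter(ctrl_grad[c],
                                                   precond_sigma)
            field.velocity = opt.step(field.velocity, ctrl_grad, lr_sc)
            comp.velocity = field.velocity
    finally:
        if log:
            log.close()

    field.velocity = best_v
    comp.velocity = best_v
    disp = integrate_velocity(field)
    jac = jacobian_determinant(disp, spacing)
    interior = jac[1:-1, 1:-1, 1:-1]
    if interior.min() <= 0:
        raise RegistrationError(
            f"non-positive Jacobian after integration "
            f"(min {interior.min():.4g})")
    # warp the nodes with the same coarse-lattice cubic displacement the
    # optimizer evaluated, so the returned mesh matches the optimized state
    disp_c = prefilter_displacement(integrate_velocity(comp))
    fitted_nodes = base_nodes + sample_displacement(disp_c, comp.affine,
                                                    base_nodes, order=3,
                                                    prefiltered=True)
    fitted = template.with_nodes(fitted_nodes)
    return RegistrationResult(init, field, fitted, trace, breakdown)


# ----------------------------------------------------------------------
# surface-target energy minimization
# ----------------------------------------------------------------------

def fit_mesh_to_surfaces(template: MultiComponentMesh,
                         targets: dict[str, np.ndarray],
                         weights: LossWeights | None = None,
                         sim_iters: int = 200, warp_iters: int = 2000,
                         lr_warp: float = 1e-2,
                         sim_lrs: tuple[float, float, float] = (0.1, 0.1, 1.0),
                         domain_spacing: float = 2.0,
                         domain_margin: float = 12.0,
                         control_spacing: int = 3,
                         integration_steps: int = 6,
                         optimize_similarity: bool = True,
                         init_velocity: np.ndarray | None = None,
                         tol: float = 1e-6,
                         log_jsonl: str | None = None,
                         ) -> RegistrationResult:
    """Fit the template to per-component surface point clouds by minimizing
    the combined chamfer + distortion + surface-regularizer objective over
    a similarity transform and a diffeomorphic b-spline velocity field.

    ``init_velocity`` accepts an externally predicted control-velocity grid
    (e.g. from a learned displacement predictor) as a warm start.
    """
    weights = weights or LossWeights()
    tgt_pts = {n: (t[0] if isinstance(t, tuple) else t)
               for n, t in targets.items()}
    for n in template.component_names:
        if n not in tgt_pts or len(tgt_pts[n]) == 0:
            raise ValueError(f"empty or missing targets for component {n!r}")

    # --- stage A: similarity --------------------------------------------
    center = template.nodes.mean(axis=0)
    tgt_all = np.concatenate([tgt_pts[n] for n in template.component_names])
    scale, rot = np.ones(3), np.zeros(3)
    trans = tgt_all.mean(axis=0) - center
    trace: list[float] = []
    if optimize_similarity:
        opt_s, opt_r, opt_t = (Adam(lr) for lr in sim_lrs)
        best = (np.inf, scale.copy(), rot.copy(), trans.copy())
        for it in range(sim_iters):
            sim = SimilarityTransform(rot, trans, scale, center)
            nodes1 = sim.apply(template.nodes)
            loss, _, g = total_mesh_loss(template, template.with_nodes(nodes1),
                                         targets, weights, need_grad=True)
            trace.append(loss)
            if loss < best[0]:
                best = (loss, scale.copy(), rot.copy(), trans.copy())
            if _stalled(trace, tol):
                break
            R = sim.rotation_matrix()
            X = template.nodes - center
            g_t = g.sum(axis=0)
            g_s = (g @ R * X).sum(axis=0)
            g_r = np.empty(3)
            for k in range(3):
                eps = 1e-5
                rp, rm = rot.copy(), rot.copy()
                rp[k] += eps
                rm[k] -= eps
                dR = (SimilarityTransform(rp).rotation_matrix()
                      - SimilarityTransform(rm).rotation_matrix()) / (2 * eps)
                g_r[k] = float(np.sum(g * ((scale * X) @ dR.T)))
            lr_sc = _cosine_decay(it, sim_iters)
            scale = np.clip(opt_s.step(scale, g_s, lr_sc), 0.2, 5.0)
            rot = opt_r.step(rot, g_r, lr_sc)
            trans = opt_t.step(trans, g_t, lr_sc)
        _, scale, rot, trans = best
    sim = SimilarityTransform(rot, trans, scale, center)
    base_nodes = sim.apply(template.nodes)

    # --- stage B: diffeomorphic refinement ------------------------------
    lo = np.minimum(base_nodes.min(axis=0), tgt_all.min(axis=0)) - domain_margin
    hi = np.maximum(base_nodes.max(axis=0), tgt_all.max(axis=0)) + domain_margin
    shape = tuple(int(np.ceil((h - l) / domain_spacing)) + 1
                  for l, h in zip(lo, hi))
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * domain_spacing
    affine[:3, 3] = lo
    field = BSplineDiffeo.zeros(shape, affine, control_spacing,
                                integration_steps)
    if init_velocity is not None:
        if init_velocity.shape != field.velocity.shape:
            raise ValueError("init_velocity has wrong control-grid shape")
        field.velocity = np.asarray(init_velocity, dtype=float).copy()

    opt = Adam(lr_warp)
    log = open(log_jsonl, "w") if log_jsonl else None
    best_v, best_loss = field.velocity.copy(), np.inf
    initial_loss = None
    breakdown: dict[str, float] = {}
    warp_trace: list[float] = []
    comp = coarse_view(field)
    try:
        for it in range(warp_iters):
            disp = integrate_velocity(comp)
            disp_c = prefilter_displacement(disp)
            nodes1 = base_nodes + sample_displacement(disp_c, comp.affine,
                                                      base_nodes, order=3,
                                                      prefiltered=True)
            loss, breakdown, g = total_mesh_loss(
                template, template.with_nodes(nodes1), targets, weights,
                need_grad=True)
            trace.append(loss)
            warp_trace.append(loss)
            if log:
                log.write(json.dumps({"iter": it, "total": loss,
                                      **breakdown}) + "\n")
            if initial_loss is None:
                initial_loss = loss
            if loss > 10 * initial_loss:
                raise RegistrationError("surface fit diverged "
                                        f"(loss {loss:.3g} vs initial "
                                        f"{initial_loss:.3g})")
            if loss < best_loss:
                best_loss, best_v = loss, field.velocity.copy()
            if _stalled(warp_trace, tol):
                break
            dense_grad = _splat_vector_adjoint(base_nodes, g, comp.shape,
                                               comp.affine)
            ctrl_grad = pullback_to_controls(comp, dense_grad)
            field.velocity = opt.step(field.velocity, ctrl_grad,
                                      _cosine_decay(it, warp_iters))
            comp.velocity = field.velocity
    finally:
        if log:
            log.close()

    field.velocity = best_v
    comp.velocity = best_v
    disp_c = prefilter_displacement(integrate_velocity(comp))
    fitted_nodes = base_nodes + sample_displacement(disp_c, comp.affine,
                                                    base_nodes, order=3,
                                                    prefiltered=True)
    fitted = template.with_nodes(fitted_nodes)
    return RegistrationResult(sim, field, fitted, trace, breakdown)


# ----------------------------------------------------------------------
# time series and calcification
# ----------------------------------------------------------------------

def register_time_series(template: MultiComponentMesh, frames: list,
                         mode: str | None = None, **kwargs,
                         ) -> tuple[list[RegistrationResult | None],
                                    dict[int, str]]:
    """Independent per-frame fits of one template (so all frame meshes share
    node correspondence).  Returns (results, errors); a failed frame leaves
    ``None`` in its slot with the error message recorded.
    """
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    results: list[RegistrationResult | None] = []
    errors: dict[int, str] = {}
    for i, frame in enumerate(frames):
        try:
            if (mode == "labels") or (mode is None
                                      and isinstance(frame, LabelMaps)):
                sim = fit_similarity_to_labels(
                    template, frame,
                    **{k: v for k, v in kwargs.items()
                       if k in ("iters", "points_per_voxel")})
                res = fit_nonrigid_to_labels(
                    template, frame, sim,
                    **{k: v for k, v in kwargs.items()
                       if k not in ("iters", "points_per_voxel")})
            else:
                res = fit_mesh_to_surfaces(template, frame, **kwargs)
            results.append(res)
        except (RegistrationError, ValueError) as exc:  # pragma: no cover
            results.append(None)
            errors[i] = str(exc)
    return results, errors


def assign_calcified_elements(mesh: MultiComponentMesh,
                              calc: CalcificationSegmentation,
                              threshold: float = 0.5,
                              ) -> set[tuple[str, int]]:
    """Flag elements carrying calcium: the binary segmentation is trilinearly
    interpolated at every node, and an element is selected iff at least one
    of its nodes interpolates above the threshold.  Returns
    {(component name, element index)}."""
    nodal = interpolate_at_points(calc.grid, mesh.nodes, fill=0.0)
    hot = nodal > threshold
    out: set[tuple[str, int]] = set()
    for blk in mesh.components:
        flag = hot[blk.elements].any(axis=1)
        out.update((blk.name, int(i)) for i in np.nonzero(flag)[0])
    return out
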