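"""Deterministic synthetic left-heart fixtures.

An idealized geometry stands in for patient anatomy so that every pipeline
stage can be exercised against analytic ground truth: an ellipsoidal LV
myocardium shell (triangles only), a cylindrical aortic wall (one hexahedral
layer through the thickness), and three aortic-valve leaflets meshed as
hexahedral blocks with exactly three element layers through the thickness,
each element carrying its thickness direction.  Generators also produce
rasterized per-component occupancy maps, smooth known b-spline warps (ground
truth for recovery experiments), a periodic contraction cine, and blob-like
calcification masks at 0.33 mm spacing.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter

from .deformation import (BSplineDiffeo, integrate_velocity,
                          sample_displacement)
from .images import (CalcificationSegmentation, LabelMaps, VoxelImage,
                     axis_aligned_image)
from .mesh import ComponentBlock, MultiComponentMesh, sample_component_surface
from .quality import count_negative_jacobian
from .registration import rasterize_mesh


@dataclass
class FixtureSpec:
    """Geometry and perturbation parameters of the synthetic left heart.

    Dimensions follow adult anatomy at a slightly reduced scale: LV semi-axes
    ~22x22x30 mm, aortic lumen radius 11 mm with a 2 mm wall, and 0.9 mm
    leaflets (0.3 mm per element layer).
    """

    seed: int = 0
    lv_radii_mm: tuple[float, float, float] = (22.0, 22.0, 30.0)
    aorta_radius_mm: float = 11.0
    aorta_wall_mm: float = 2.0
    aorta_length_mm: float = 26.0
    aorta_base_z_mm: float = 24.0
    leaflet_thickness_mm: float = 0.9
    leaflet_sag_mm: float = 5.0
    warp_amplitude_mm: float = 3.0
    n_frames: int = 8
    contraction_fraction: float = 0.3
    calc_blob_count: int = 3

    def __post_init__(self) -> None:
        dims = (*self.lv_radii_mm, self.aorta_radius_mm, self.aorta_wall_mm,
                self.aorta_length_mm, self.leaflet_thickness_mm)
        if any(d <= 0 for d in dims):
            raise ValueError("all fixture dimensions must be positive")
        if self.warp_amplitude_mm < 0:
            raise ValueError("warp amplitude must be nonnegative")
        if self.warp_amplitude_mm > self.min_feature_mm / 2:
            raise ValueError("warp amplitude exceeds half the smallest "
                             "feature size; ground-truth warp would not be "
                             "safely diffeomorphic at mesh scale")

    @property
    def min_feature_mm(self) -> float:
        return min(min(self.lv_radii_mm), self.aorta_radius_mm,
                   self.aorta_length_mm)


# ----------------------------------------------------------------------
# template
# ----------------------------------------------------------------------

def _build_aorta(spec: FixtureSpec, n_theta: int = 24, n_z: int = 8,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r_in = spec.aorta_radius_mm
    r_out = r_in + spec.aorta_wall_mm
    theta = np.arange(n_theta) * 2 * np.pi / n_theta
    z = spec.aorta_base_z_mm + np.linspace(0, spec.aorta_length_mm, n_z + 1)
    nodes = []
    for radius in (r_in, r_out):
        for zz in z:
            for th in theta:
                nodes.append([radius * np.cos(th), radius * np.sin(th), zz])
    nodes = np.array(nodes)
    n_ring = n_theta
    n_shell = n_ring * (n_z + 1)

    def nid(shell: int, iz: int, it: int) -> int:
        return shell * n_shell + iz * n_ring + (it % n_theta)

    hexes, aniso = [], []
    for iz in range(n_z):
        for it in range(n_theta):
            hexes.append([nid(0, iz, it), nid(1, iz, it), nid(1, iz, it + 1),
                          nid(0, iz, it + 1),
                          nid(0, iz + 1, it), nid(1, iz + 1, it),
                          nid(1, iz + 1, it + 1), nid(0, iz + 1, it + 1)])
            thc = theta[it] + np.pi / n_theta
            aniso.append([np.cos(thc), np.sin(thc), 0.0])
    return nodes, np.array(hexes), np.array(aniso)


def _leaflet_midsurface(spec: FixtureSpec, j: int, nu: int, nv: int,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Mid-surface points and unit normals of leaflet j on an
    (nu+1)x(nv+1) parameter grid."""
    r = spec.aorta_radius_mm
    th0 = j * 2 * np.pi / 3
    gap = np.deg2rad(6.0)
    u = np.linspace(0.0, 1.0, nu + 1)
    v = np.linspace(th0 + gap, th0 + 2 * np.pi / 3 - gap, nv + 1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    rho = r * (1 - uu) + 0.15 * r * uu
    z = spec.aorta_base_z_mm + 2.0 - spec.leaflet_sag_mm * np.sin(np.pi * uu / 1.6)
    pts = np.stack([rho * np.cos(vv), rho * np.sin(vv), z], axis=-1)
    # normals from parameter tangents (du x dv), central differences
    tu = np.gradient(pts, axis=0)
    tv = np.gradient(pts, axis=1)
    nrm = np.cross(tu, tv)
    nrm /= np.linalg.norm(nrm, axis=-1, keepdims=True)
    return pts, nrm


def _build_leaflet(spec: FixtureSpec, j: int, nu: int = 6, nv: int = 8,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mid, nrm = _leaflet_midsurface(spec, j, nu, nv)
    t = spec.leaflet_thickness_mm
    offsets = np.array([-t / 2, -t / 6, t / 6, t / 2])
    sheets = mid[None] + offsets[:, None, None, None] * nrm[None]
    nodes = sheets.reshape(-1, 3)
    n_sheet = (nu + 1) * (nv + 1)

    def nid(sheet: int, iu: int, iv: int) -> int:
        return sheet * n_sheet + iu * (nv + 1) + iv

    hexes, aniso = [], []
    for layer in range(3):          # layer-major: first third is layer 0
        for iu in range(nu):
            for iv in range(nv):
                hexes.append([
                    nid(layer, iu, iv), nid(layer, iu + 1, iv),
                    nid(layer, iu + 1, iv + 1), nid(layer, iu, iv + 1),
                    nid(layer + 1, iu, iv), nid(layer + 1, iu + 1, iv),
                    nid(layer + 1, iu + 1, iv + 1), nid(layer + 1, iu, iv + 1)])
                d = (nrm[iu, iv] + nrm[iu + 1, iv] + nrm[iu, iv + 1]
                     + nrm[iu + 1, iv + 1])
                aniso.append(d / np.linalg.norm(d))
    return nodes, np.array(hexes), np.array(aniso)


def make_template(spec: FixtureSpec | None = None) -> MultiComponentMesh:
    """Idealized left-heart template with the fixed 5-component structure."""
    spec = spec or FixtureSpec()
    lv = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    lv_nodes = lv.vertices * np.asarray(spec.lv_radii_mm)
    lv_faces = np.asarray(lv.faces)

    blocks, all_nodes = [], [lv_nodes]
    blocks.append(ComponentBlock("lv", "triangle", lv_faces))
    offset = len(lv_nodes)

    nodes, hexes, aniso = _build_aorta(spec)
    blocks.append(ComponentBlock("aorta", "hexahedron", hexes + offset, aniso))
    all_nodes.append(nodes)
    offset += len(nodes)

    for j in range(3):
        nodes, hexes, aniso = _build_leaflet(spec, j)
        blocks.append(ComponentBlock(f"leaflet{j + 1}", "hexahedron",
                                     hexes + offset, aniso))
        all_nodes.append(nodes)
        offset += len(nodes)

    mesh = MultiComponentMesh(np.concatenate(all_nodes), blocks)
    if count_negative_jacobian(mesh) != 0:
        raise ValueError("infeasible fixture dimensions: template has "
                         "inverted elements")
    return mesh


# ----------------------------------------------------------------------
# label maps
# ----------------------------------------------------------------------

def leaflet_thickness_estimate(mesh: MultiComponentMesh) -> float:
    """Mean through-thickness extent of the leaflet blocks (anisotropy-
    projected bottom-to-top corner vectors, summed over the 3 layers)."""
    total = []
    for name in ("leaflet1", "leaflet2", "leaflet3"):
        blk = mesh.component(name)
        c = mesh.nodes[blk.elements]
        step = np.einsum("ei,ei->e", c[:, 4] - c[:, 0], blk.anisotropy)
        total.append(np.abs(step).mean() * 3)
    return float(np.mean(total))


def fixture_lattice(mesh: MultiComponentMesh, spacing_mm: float,
                    margin_mm: float = 8.0) -> VoxelImage:
    lo = mesh.nodes.min(axis=0) - margin_mm
    hi = mesh.nodes.max(axis=0) + margin_mm
    shape = tuple(int(np.ceil((h - l) / spacing_mm)) + 1
                  for l, h in zip(lo, hi))
    return axis_aligned_image(np.zeros(shape), spacing_mm, lo)


def make_labelmaps(template: MultiComponentMesh, spacing_mm: float = 1.5,
                   margin_mm: float = 8.0, binarize: bool = False) -> LabelMaps:
    """Rasterized per-component occupancy at the requested spacing.

    Components may overlap at interfaces.  Raises if the lattice is too
    coarse to resolve the leaflets (a slab thinner than ~0.55 voxel would
    vanish under the 0.5 binarization threshold).
    """
    thick = leaflet_thickness_estimate(template)
    if spacing_mm > thick / 0.55:
        raise ValueError(f"spacing {spacing_mm} mm too coarse to resolve "
                         f"{thick:.2f} mm leaflets")
    lat = fixture_lattice(template, spacing_mm, margin_mm)
    return rasterize_mesh(template, lat, binarize=binarize)


# ----------------------------------------------------------------------
# ground-truth warps and cine
# ----------------------------------------------------------------------

def make_synthetic_warp(spec: FixtureSpec | None = None,
                        template: MultiComponentMesh | None = None,
                        domain_spacing_mm: float = 2.0,
                        control_spacing_vox: int = 6,
                        margin_mm: float = 12.0,
                        ) -> tuple[BSplineDiffeo, MultiComponentMesh]:
    """Seeded smooth diffeomorphic warp plus the warped template.

    A random control-lattice velocity is smoothed, integrated, and scaled so
    the maximum template-node displacement equals ``warp_amplitude_mm``.
    The warped mesh is guaranteed free of inverted elements.
    """
    spec = spec or FixtureSpec()
    if template is None:
        template = make_template(spec)
    lat = fixture_lattice(template, domain_spacing_mm, margin_mm)
    diffeo = BSplineDiffeo.zeros(lat.shape, lat.affine, control_spacing_vox)
    rng = np.random.default_rng(spec.seed)
    raw = rng.normal(size=diffeo.velocity.shape)
    for c in range(3):
        raw[c] = gaussian_filter(raw[c], sigma=1.0)
    diffeo.velocity = raw
    if spec.warp_amplitude_mm == 0:
        diffeo.velocity = np.zeros_like(raw)
        return diffeo, template.with_nodes(template.nodes.copy())
    # two fixed-point passes: displacement is nearly linear in the velocity
    for _ in range(2):
        disp = integrate_velocity(diffeo)
        d = sample_displacement(disp, diffeo.affine, template.nodes)
        peak = np.linalg.norm(d, axis=1).max()
        diffeo.velocity *= spec.warp_amplitude_mm / peak
    disp = integrate_velocity(diffeo)
    warped = template.with_nodes(
        template.nodes + sample_displacement(disp, diffeo.affine,
                                             template.nodes))
    if count_negative_jacobian(warped) != 0:
        raise ValueError("synthetic warp inverted elements; lower amplitude")
    return diffeo, warped


def lv_cavity_volume(mesh: MultiComponentMesh) -> float:
    """Volume enclosed by the LV shell (divergence theorem), in mm^3."""
    tris = mesh.component("lv").elements
    a, b, c = (mesh.nodes[tris[:, i]] for i in range(3))
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0))


def cine_frame(spec: FixtureSpec, template: MultiComponentMesh,
               frame: int) -> MultiComponentMesh:
    """One frame of the periodic contraction: radial LV scaling about the
    LV centre plus a leaflet opening modulation; frame n equals frame 0."""
    phase = 2 * np.pi * frame / spec.n_frames
    squeeze = (1 - np.cos(phase)) / 2          # 0 at frame 0, 1 mid-cycle
    s_lv = 1.0 - spec.contraction_fraction * squeeze
    nodes = template.nodes.copy()
    lv_idx = template.component_nodes("lv")
    lv_center = nodes[lv_idx].mean(axis=0)
    nodes[lv_idx] = lv_center + s_lv * (nodes[lv_idx] - lv_center)
    open_amount = 0.12 * squeeze               # leaflets swing open radially
    for name in ("leaflet1", "leaflet2", "leaflet3"):
        idx = template.component_nodes(name)
        xy = nodes[idx, :2]
        nodes[idx, :2] = xy * (1 + open_amount)
    return template.with_nodes(nodes)


@dataclass
class CineFixture:
    meshes: list[MultiComponentMesh]
    targets: list[dict[str, np.ndarray]]
    trajectories: np.ndarray  # (n_frames, n_nodes, 3) ground truth


def make_cine(spec: FixtureSpec | None = None,
              template: MultiComponentMesh | None = None,
              points_per_component: int = 1500) -> CineFixture:
    """Periodic synthetic cardiac cycle with ground-truth node trajectories."""
    spec = spec or FixtureSpec()
    if spec.n_frames < 1:
        raise ValueError("need at least one frame")
    if template is None:
        template = make_template(spec)
    meshes = [cine_frame(spec, template, f) for f in range(spec.n_frames)]
    targets = [{n: sample_component_surface(m, n, points_per_component)
                for n in m.component_names} for m in meshes]
    traj = np.stack([m.nodes for m in meshes])
    return CineFixture(meshes, targets, traj)


# ----------------------------------------------------------------------
# calcification
# ----------------------------------------------------------------------

def make_calcification(spec: FixtureSpec | None = None,
                       template: MultiComponentMesh | None = None,
                       spacing_mm: float = 0.33,
                       margin_mm: float = 4.0) -> CalcificationSegmentation:
    """Seeded ellipsoidal calcium blobs attached to the leaflet
    mid-surfaces, rasterized as a binary mask at 0.33 mm spacing."""
    spec = spec or FixtureSpec()
    if template is None:
        template = make_template(spec)
    rng = np.random.default_rng(spec.seed + 17)
    leaf_names = ("leaflet1", "leaflet2", "leaflet3")
    lo = np.min([template.nodes[template.component_nodes(n)].min(axis=0)
                 for n in leaf_names], axis=0) - margin_mm
    hi = np.max([template.nodes[template.component_nodes(n)].max(axis=0)
                 for n in leaf_names], axis=0) + margin_mm
    shape = tuple(int(np.ceil((h - l) / spacing_mm)) + 1
                  for l, h in zip(lo, hi))
    grid = axis_aligned_image(np.zeros(shape), spacing_mm, lo)
    if spec.calc_blob_count > 0:
        centers, radii = [], []
        for b in range(spec.calc_blob_count):
            name = leaf_names[b % 3]
            idx = template.component_nodes(name)
            for _ in range(50):
                c = template.nodes[rng.choice(idx)]
                r = rng.uniform(1.2, 2.2, size=3)
                if all(np.linalg.norm(c - c2) > r.max() + r2.max() + 3 * spacing_mm
                       for c2, r2 in zip(centers, radii)):
                    break
            centers.append(c)
            radii.append(r)
        ii = np.indices(shape).reshape(3, -1).T
        world = grid.voxel_to_world(ii.astype(float))
        mask = np.zeros(len(world), dtype=bool)
        for c, r in zip(centers, radii):
            mask |= np.sum(((world - c) / r) ** 2, axis=1) <= 1.0
        grid.values[...] = mask.reshape(shape).astype(float)
    return CalcificationSegmentation(grid)
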