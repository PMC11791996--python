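"""Similarity transforms and diffeomorphic b-spline deformation fields.

The non-rigid deformation model is a stationary velocity field parameterized
by cubic b-spline coefficients on a control lattice with isotropic spacing
of (by default) 3 voxels.  The velocity is integrated by scaling and
squaring, which makes the resulting displacement a diffeomorphism: smooth,
invertible, with positive Jacobian determinant — the property that prevents
mesh element inversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from .images import VoxelImage


@dataclass
class SimilarityTransform:
    """Rotation (axis-angle, radians), translation (mm), anisotropic scale.

    Acts as y = R (s * (x - c)) + c + t about a fixed centre c.
    Axis-angle keeps the rotation parameterization singularity-free for the
    small rotations seen in cardiac registration.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("scale must be positive componentwise")

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(self.rotation).as_matrix()

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world->world matrix."""
        R = self.rotation_matrix()
        A = R @ np.diag(self.scale)
        m = np.eye(4)
        m[:3, :3] = A
        m[:3, 3] = self.center + self.translation - A @ self.center
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        R = self.rotation_matrix()
        return (self.scale * (points - self.center)) @ R.T \
            + self.center + self.translation

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: getattr(self, k).tolist() for k in
                       ("rotation", "translation", "scale", "center")}, fh)

    @classmethod
    def from_json(cls, path: str) -> "SimilarityTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**{k: np.asarray(v) for k, v in d.items()})


@dataclass
class BSplineDiffeo:
    """Stationary velocity on a control lattice over a reference voxel grid.

    ``velocity`` has shape (3, ncx, ncy, ncz) in mm; control point k sits at
    voxel coordinate (k - 1) * control_spacing, so one ring of controls lies
    outside the domain on each side.  The reference lattice must be
    axis-aligned with isotropic spacing.
    """

    velocity: np.ndarray
    shape: tuple[int, int, int]
    affine: np.ndarray
    control_spacing: int = 3
    integration_steps: int = 6

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        lin = self.affine[:3, :3]
        sp = np.linalg.norm(lin, axis=0)
        if not (np.allclose(lin, np.diag(np.diag(lin))) and
                np.allclose(sp, sp[0])):
            raise ValueError("deformation domain must be axis-aligned isotropic")
        need = tuple(int(np.ceil((s - 1) / self.control_spacing)) + 4
                     for s in self.shape)
        if self.velocity.shape != (3, *need):
            raise ValueError(f"control grid must have shape (3, {need}); "
                             f"got {self.velocity.shape}")

    @property
    def spacing(self) -> float:
        return float(np.linalg.norm(self.affine[:3, :3], axis=0)[0])

    @classmethod
    def zeros(cls, shape: tuple[int, int, int], affine: np.ndarray,
              control_spacing: int = 3, integration_steps: int = 6,
              ) -> "BSplineDiffeo":
        nc = tuple(int(np.ceil((s - 1) / control_spacing)) + 4 for s in shape)
        return cls(np.zeros((3, *nc)), tuple(shape), np.asarray(affine, float),
                   control_spacing, integration_steps)

    def control_coords(self) -> np.ndarray:
        """Voxel coordinates of the control points, per axis."""
        return np.array([
            (np.arange(n) - 1) * self.control_spacing
            for n in self.velocity.shape[1:]], dtype=object)

    def save_displacement(self, path: str) -> None:
        """Serialize the integrated displacement as a 3-component NIfTI."""
        import nibabel as nib
        disp = integrate_velocity(self)
        nib.save(nib.Nifti1Image(np.moveaxis(disp, 0, -1).astype(np.float32),
                                 self.affine), path)


def densify_velocity(field: BSplineDiffeo) -> np.ndarray:
    """Cubic b-spline interpolation of the control velocities onto the
    full voxel lattice.  Returns (3, *shape) in mm.

    The control array stores spline *coefficients*, so evaluation is
    map_coordinates with prefiltering disabled (pure basis summation).
    """
    sp = field.control_spacing
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in field.shape],
                        indexing="ij")
    coords = [g / sp + 1.0 for g in grids]
    out = np.empty((3, *field.shape))
    for c in range(3):
        out[c] = map_coordinates(field.velocity[c], coords, order=3,
                                 prefilter=False, mode="nearest")
    return out


def _compose_displacement(u: np.ndarray, v: np.ndarray,
                          grid: list[np.ndarray]) -> np.ndarray:
    """Sample v at (x + u) and return it, both fields in voxel units."""
    coords = [grid[a] + u[a] for a in range(3)]
    out = np.empty_like(v)
    for c in range(3):
        out[c] = map_coordinates(v[c], coords, order=1, mode="nearest")
    return out


def integrate_velocity(field: BSplineDiffeo,
                       dense_velocity: np.ndarray | None = None) -> np.ndarray:
    """Exponentiate the stationary velocity by scaling and squaring.

    The velocity is halved ``integration_steps`` times, then the small
    displacement is composed with itself that many times.  Returns the dense
    displacement (3, *shape) in mm.
    """
    vel = densify_velocity(field) if dense_velocity is None else dense_velocity
    sp = field.spacing
    u = vel / sp / (2.0 ** field.integration_steps)  # voxel units
    grid = list(np.meshgrid(*[np.arange(s, dtype=float) for s in field.shape],
                            indexing="ij"))
    for _ in range(field.integration_steps):
        u = u + _compose_displacement(u, u, grid)
    return u * sp


def jacobian_determinant(displacement_mm: np.ndarray,
                         spacing: float) -> np.ndarray:
    """det(I + du/dx) of the map x -> x + u on the voxel lattice."""
    u = displacement_mm / spacing
    J = np.empty(u.shape[1:] + (3, 3))
    for c in range(3):
        g = np.gradient(u[c])
        for a in range(3):
            J[..., c, a] = g[a]
    J[..., 0, 0] += 1.0
    J[..., 1, 1] += 1.0
    J[..., 2, 2] += 1.0
    return np.linalg.det(J)


def coarse_view(field: BSplineDiffeo) -> BSplineDiffeo:
    """The same continuous velocity field evaluated on a lattice decimated
    to the control spacing (control spacing becomes 1 coarse voxel).

    Shares the coefficient array with ``field``; integration and gradient
    pullback on this view are ~spacing^3 times cheaper, at an interpolation
    error quadratic in the (smooth) field's control spacing.
    """
    sp = field.control_spacing
    if sp == 1:
        return field
    shape = tuple(int(np.ceil((s - 1) / sp)) + 1 for s in field.shape)
    affine = field.affine.copy()
    affine[:3, :3] *= sp
    return BSplineDiffeo(field.velocity, shape, affine, control_spacing=1,
                         integration_steps=field.integration_steps)


def displacement_image(field: BSplineDiffeo) -> VoxelImage:
    """Reference-lattice image carrier (for world<->voxel bookkeeping)."""
    return VoxelImage(np.zeros(field.shape), field.affine)


def sample_displacement(displacement_mm: np.ndarray, affine: np.ndarray,
                        points_mm: np.ndarray, order: int = 1,
                        prefiltered: bool = False) -> np.ndarray:
    """Sample a dense (3, *shape) mm displacement at world points
    (trilinear by default; ``order=3`` for smooth fields on coarse
    lattices, where cubic interpolation is markedly more accurate).

    ``prefiltered=True`` declares that the field already holds spline
    coefficients (see :func:`prefilter_displacement`), skipping the
    per-call prefilter pass."""
    inv = np.linalg.inv(affine)
    vox = points_mm @ inv[:3, :3].T + inv[:3, 3]
    out = np.empty_like(points_mm)
    for c in range(3):
        out[:, c] = map_coordinates(displacement_mm[c], vox.T, order=order,
                                    mode="nearest",
                                    prefilter=not prefiltered)
    return out


def prefilter_displacement(displacement_mm: np.ndarray) -> np.ndarray:
    """Cubic spline coefficients of a dense field, for repeated sampling."""
    from scipy.ndimage import spline_filter
    return np.stack([spline_filter(displacement_mm[c], order=3,
                                   mode="nearest") for c in range(3)])


def warp_points(points_mm: np.ndarray, sim: SimilarityTransform | None,
                diffeo: BSplineDiffeo | None = None,
                displacement_mm: np.ndarray | None = None) -> np.ndarray:
    """Apply the similarity, then add the diffeomorphic displacement sampled
    at the transformed location (the fixed composition order of the
    two-stage registration)."""
    pts = np.asarray(points_mm, dtype=float)
    if sim is not None:
        pts = sim.apply(pts)
    if diffeo is not None:
        if displacement_mm is None:
            displacement_mm = integrate_velocity(diffeo)
        pts = pts + sample_displacement(displacement_mm, diffeo.affine, pts)
    return pts


def bending_energy(field: BSplineDiffeo | np.ndarray,
                   displacement_mm: np.ndarray | None = None) -> float:
    """Second-order (bending) smoothness of the deformation field.

    Mean over voxels of the squared pure second derivatives plus doubly
    weighted squared mixed second derivatives, summed over the three vector
    components.  Derivatives are central differences in voxel units with
    one-sided stencils at the boundary, so any globally affine field has
    exactly zero bending energy.
    """
    if isinstance(field, BSplineDiffeo):
        phi = (integrate_velocity(field) if displacement_mm is None
               else displacement_mm) / field.spacing
    else:
        phi = np.asarray(field, dtype=float)
    if phi.ndim != 4 or phi.shape[0] != 3:
        raise ValueError("expected a (3, nx, ny, nz) field")
    if min(phi.shape[1:]) < 3:
        raise ValueError("domain smaller than the finite-difference stencil")
    total = 0.0
    n_vox = np.prod(phi.shape[1:])
    for c in range(3):
        first = np.gradient(phi[c])
        for a in range(3):
            for b in range(a, 3):
                if a == b:
                    second = _second_difference(phi[c], a)
                    w = 1.0
                else:
                    second = np.gradient(first[a], axis=b)
                    w = 2.0
                total += w * float(np.sum(second ** 2))
    return total / n_vox


def _second_difference(arr: np.ndarray, axis: int) -> np.ndarray:
    """Pure second derivative: central stencil, one-sided at the boundary
    (exact for quadratics everywhere)."""
    a = np.moveaxis(arr, axis, 0)
    out = np.empty_like(a)
    out[1:-1] = a[2:] - 2 * a[1:-1] + a[:-2]
    out[0] = a[0] - 2 * a[1] + a[2]
    out[-1] = a[-1] - 2 * a[-2] + a[-3]
    return np.moveaxis(out, 0, axis)


def bending_energy_gradient(phi: np.ndarray) -> tuple[float, np.ndarray]:
    """Bending energy and its gradient w.r.t. the dense field.

    Uses interior central-difference stencils (replicated boundary), whose
    adjoint is correlation with the same symmetric kernels; boundary rows
    differ slightly from the one-sided stencils of :func:`bending_energy`,
    which only matters at the domain edge where registration fixtures are
    zero anyway.
    """
    from scipy.ndimage import correlate1d
    k2 = np.array([1.0, -2.0, 1.0])
    k1 = np.array([0.5, 0.0, -0.5])
    n_vox = np.prod(phi.shape[1:])
    total = 0.0
    grad = np.zeros_like(phi)
    for c in range(3):
        for a in range(3):
            for b in range(a, 3):
                if a == b:
                    d = correlate1d(phi[c], k2, axis=a, mode="nearest")
                    w = 1.0
                else:
                    d = correlate1d(correlate1d(phi[c], k1, axis=a,
                                                mode="nearest"),
                                    k1, axis=b, mode="nearest")
                    w = 2.0
                total += w * float(np.sum(d ** 2))
                # adjoint: correlate the residual with the same kernels
                if a == b:
                    g = correlate1d(d, k2, axis=a, mode="nearest")
                else:
                    g = correlate1d(correlate1d(d, k1, axis=b, mode="nearest"),
                                    k1, axis=a, mode="nearest")
                grad[c] += 2.0 * w * g
    return total / n_vox, grad / n_vox


def pullback_to_controls(field: BSplineDiffeo,
                         dense_grad: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`densify_velocity`: accumulate a dense-lattice
    gradient onto the control coefficients.

    Because control spacing is an integer number of voxels, the adjoint is a
    separable correlation with the sampled cubic b-spline kernel followed by
    striding to the control lattice.
    """
    from scipy.ndimage import correlate1d
    sp = field.control_spacing
    # cubic b-spline sampled at integer voxel offsets m/sp, support |t| < 2
    m = np.arange(-2 * sp + 1, 2 * sp)
    t = np.abs(m / sp)
    kern = np.where(t < 1, 2 / 3 - t**2 + t**3 / 2,
                    np.where(t < 2, (2 - t) ** 3 / 6, 0.0))
    out = np.zeros_like(field.velocity)
    nc = field.velocity.shape[1:]
    pad = 3 * sp  # covers controls whose voxel position lies outside the grid
    idx = [(np.arange(n) - 1) * sp + pad for n in nc]
    for c in range(3):
        g = np.pad(dense_grad[c], pad)
        for ax in range(3):
            g = correlate1d(g, kern, axis=ax, mode="constant", cval=0.0)
        out[c] = g[np.ix_(idx[0], idx[1], idx[2])]
    return out
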