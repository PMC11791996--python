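"""Voxel images, multilabel occupancy maps and interpolation primitives.

World coordinates are millimetres, voxel indices are 0-based, and the affine
maps voxel index -> world (NIfTI convention).  Cardiac CT intensities are
normalized by the fixed linear window [-158, 864] HU -> [0, 1] that brackets
soft tissue through dense calcification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy.ndimage import map_coordinates

HU_WINDOW = (-158.0, 864.0)

#: fixed component order: LV myocardium shell, aortic wall, three AV leaflets
COMPONENT_NAMES = ("lv", "aorta", "leaflet1", "leaflet2", "leaflet3")


@dataclass
class VoxelImage:
    """A 3D scalar grid with a voxel->world affine (mm)."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is degenerate")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def save(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), path)

    @classmethod
    def load(cls, path: str) -> "VoxelImage":
        img = nib.load(path)
        return cls(np.asarray(img.dataobj, dtype=float), np.asarray(img.affine))


def axis_aligned_image(values: np.ndarray, spacing: float | np.ndarray,
                       origin: np.ndarray | None = None) -> VoxelImage:
    """Convenience constructor for an axis-aligned grid."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    if origin is not None:
        affine[:3, 3] = np.asarray(origin, dtype=float)
    return VoxelImage(values, affine)


@dataclass
class LabelMaps:
    """Per-component soft occupancy grids on one shared lattice.

    Components may overlap (e.g. leaflets attached to the aortic wall), so
    each component keeps its own grid rather than an argmax map.
    """

    components: dict[str, np.ndarray]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if tuple(self.components) != COMPONENT_NAMES:
            raise ValueError(f"components must be ordered {COMPONENT_NAMES}")
        shapes = {g.shape for g in self.components.values()}
        if len(shapes) != 1:
            raise ValueError("all component grids must share one lattice")
        for name, g in self.components.items():
            if g.min() < -1e-9 or g.max() > 1 + 1e-9:
                raise ValueError(f"occupancy of {name!r} outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.components.values())).shape

    def grid(self, name: str) -> VoxelImage:
        return VoxelImage(self.components[name], self.affine)

    def union(self) -> VoxelImage:
        stack = np.stack(list(self.components.values()))
        return VoxelImage(stack.max(axis=0), self.affine)

    def save(self, path: str) -> None:
        """Write as a 4D NIfTI stack in the fixed component order."""
        stack = np.stack([g for g in self.components.values()], axis=-1)
        nib.save(nib.Nifti1Image(stack.astype(np.float32), self.affine), path)

    @classmethod
    def load(cls, path: str) -> "LabelMaps":
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        comps = {n: data[..., i] for i, n in enumerate(COMPONENT_NAMES)}
        return cls(comps, np.asarray(img.affine))

    def save_components(self, directory: str) -> None:
        """Write one 3D NIfTI per component (<name>.nii.gz)."""
        import os
        os.makedirs(directory, exist_ok=True)
        for name, g in self.components.items():
            nib.save(nib.Nifti1Image(g.astype(np.float32), self.affine),
                     os.path.join(directory, f"{name}.nii.gz"))

    @classmethod
    def load_components(cls, directory: str) -> "LabelMaps":
        import os
        comps, affine = {}, None
        for name in COMPONENT_NAMES:
            img = nib.load(os.path.join(directory, f"{name}.nii.gz"))
            comps[name] = np.asarray(img.dataobj, dtype=float)
            affine = np.asarray(img.affine)
        return cls(comps, affine)


@dataclass
class CalcificationSegmentation:
    """Binary calcium mask, conventionally at ~0.33 mm isotropic spacing."""

    grid: VoxelImage

    def __post_init__(self) -> None:
        vals = self.grid.values
        if not np.all((vals == 0) | (vals == 1)):
            raise ValueError("calcification mask must be binary")


def normalize_intensity(image: VoxelImage) -> VoxelImage:
    """Map CT Hounsfield units linearly so [-158, 864] HU -> [0, 1].

    Values outside the window are clamped, keeping normalized inputs bounded.
    """
    if not np.all(np.isfinite(image.values)):
        raise ValueError("image contains non-finite voxels")
    lo, hi = HU_WINDOW
    out = np.clip((image.values - lo) / (hi - lo), 0.0, 1.0)
    return VoxelImage(out, image.affine.copy())


def resample_isotropic(image: VoxelImage, spacing_mm: float, fov_voxels: int,
                       center_mm: np.ndarray, fill: float | None = None) -> VoxelImage:
    """Trilinearly resample onto an isotropic fov^3 grid centred at ``center_mm``.

    ``fill`` is the out-of-bounds padding value; ``None`` uses the image
    minimum (background semantics for normalized CT).
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if fov_voxels < 2:
        raise ValueError("fov must be at least 2 voxels")
    fill_val = float(image.values.min()) if fill is None else float(fill)
    center = np.asarray(center_mm, dtype=float)
    origin = center - spacing_mm * (fov_voxels - 1) / 2.0
    out = axis_aligned_image(np.zeros((fov_voxels,) * 3), spacing_mm, origin)
    idx = np.indices(out.shape, dtype=float).reshape(3, -1).T
    world = out.voxel_to_world(idx)
    src = image.world_to_voxel(world)
    vals = map_coordinates(image.values, src.T, order=1, mode="constant",
                           cval=fill_val)
    out.values[...] = vals.reshape(out.shape)
    return out


def sample_crop_center(label_maps: LabelMaps, crop_width_mm: float,
                       rng_seed: int) -> np.ndarray:
    """Draw a crop centre for translation augmentation.

    Isotropic 3D Gaussian centred at the labels' bounding-box centre with
    standard deviation crop_width/3.
    """
    union = label_maps.union()
    nz = np.argwhere(union.values > 0)
    if nz.size == 0:
        raise ValueError("label maps are empty")
    lo = union.voxel_to_world(nz.min(axis=0))[0]
    hi = union.voxel_to_world(nz.max(axis=0))[0]
    center = (lo + hi) / 2.0
    rng = np.random.default_rng(rng_seed)
    return center + rng.normal(0.0, crop_width_mm / 3.0, size=3)


def interpolate_at_points(grid: VoxelImage, points_mm: np.ndarray,
                          fill: float = 0.0) -> np.ndarray:
    """Trilinear interpolation at world-space points; out-of-bounds -> ``fill``."""
    vox = grid.world_to_voxel(points_mm)
    return map_coordinates(grid.values, vox.T, order=1, mode="constant",
                           cval=fill)
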