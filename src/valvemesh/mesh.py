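"""Fixed-topology multi-component left-heart mesh.

The template holds five named components: the LV myocardium as a pure
surface shell (triangles), the aortic wall as a hexahedral solid, and three
aortic-valve leaflets as hexahedral blocks with exactly three element layers
through the thickness.  Deformation moves node positions only; connectivity
is immutable.  Each hexahedral element carries a unit anisotropy direction
(its thickness direction) used by the anisotropic distortion energy.

Meshes serialize to legacy ASCII VTK unstructured grids with an integer
cell-data field "component" and cell-data vectors "anisotropy".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import COMPONENT_NAMES

VTK_TRIANGLE = 5
VTK_HEXAHEDRON = 12

# Right-handed corner edge triples of a hexahedron in VTK node order:
# for corner c, the three emanating edges (to HEX_CORNER_EDGES[c]) form a
# positively oriented frame on an axis-aligned cube.
HEX_CORNER_EDGES = (
    (1, 3, 4), (2, 0, 5), (3, 1, 6), (0, 2, 7),
    (7, 5, 0), (4, 6, 1), (5, 7, 2), (6, 4, 3),
)

# quad faces of a hexahedron (outward-oriented for a positively oriented hex)
HEX_FACES = (
    (0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
    (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7),
)

HEX_EDGES = (
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
)


@dataclass
class ComponentBlock:
    """One named element block: triangles (surface) or hexahedra (solid)."""

    name: str
    kind: str  # "triangle" | "hexahedron"
    elements: np.ndarray
    anisotropy: np.ndarray | None = None  # (E, 3) unit vectors, hex only

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=np.int64)
        n_corner = {"triangle": 3, "hexahedron": 8}[self.kind]
        if self.elements.ndim != 2 or self.elements.shape[1] != n_corner:
            raise ValueError(f"{self.name}: bad element array for {self.kind}")
        if self.anisotropy is not None:
            self.anisotropy = np.asarray(self.anisotropy, dtype=float)
            if self.anisotropy.shape != (len(self.elements), 3):
                raise ValueError(f"{self.name}: anisotropy shape mismatch")
            norms = np.linalg.norm(self.anisotropy, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError(f"{self.name}: anisotropy must be unit vectors")


@dataclass
class MultiComponentMesh:
    nodes: np.ndarray
    components: list[ComponentBlock]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        for blk in self.components:
            if blk.elements.size and blk.elements.max() >= len(self.nodes):
                raise ValueError(f"{blk.name}: element references missing node")

    # -- access ---------------------------------------------------------
    def component(self, name: str) -> ComponentBlock:
        for blk in self.components:
            if blk.name == name:
                return blk
        raise KeyError(name)

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(blk.name for blk in self.components)

    def with_nodes(self, nodes: np.ndarray) -> "MultiComponentMesh":
        """Same topology, new node positions (deformation never edits connectivity)."""
        nodes = np.asarray(nodes, dtype=float)
        if nodes.shape != self.nodes.shape:
            raise ValueError("node array shape must be preserved")
        return MultiComponentMesh(nodes, self.components)

    def hex_blocks(self) -> list[ComponentBlock]:
        return [b for b in self.components if b.kind == "hexahedron"]

    def all_hexes(self) -> np.ndarray:
        blocks = [b.elements for b in self.hex_blocks()]
        return np.concatenate(blocks) if blocks else np.zeros((0, 8), np.int64)

    def all_anisotropy(self) -> np.ndarray:
        out = []
        for b in self.hex_blocks():
            if b.anisotropy is None:
                raise ValueError(f"{b.name}: missing anisotropy directions")
            out.append(b.anisotropy)
        return np.concatenate(out) if out else np.zeros((0, 3))

    def component_nodes(self, name: str) -> np.ndarray:
        """Unique node indices used by one component."""
        return np.unique(self.component(name).elements)

    # -- surfaces -------------------------------------------------------
    def surface_faces(self, name: str) -> np.ndarray:
        """Triangulated outer surface of a component.

        Triangle blocks are returned as-is; for hex blocks the boundary quads
        (faces used by exactly one element) are split into two triangles.
        """
        blk = self.component(name)
        if blk.kind == "triangle":
            return blk.elements.copy()
        quads = boundary_quads(blk.elements)
        return np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])

    def component_edges(self, name: str) -> np.ndarray:
        blk = self.component(name)
        if blk.kind == "triangle":
            e = np.concatenate([blk.elements[:, [0, 1]], blk.elements[:, [1, 2]],
                                blk.elements[:, [2, 0]]])
        else:
            e = np.concatenate([blk.elements[:, list(p)] for p in HEX_EDGES])
        return np.unique(np.sort(e, axis=1), axis=0)

    def all_edges(self) -> np.ndarray:
        return np.unique(np.concatenate(
            [self.component_edges(b.name) for b in self.components]), axis=0)


def boundary_quads(hexes: np.ndarray) -> np.ndarray:
    """Outward-oriented quad faces used by exactly one hexahedron."""
    faces = np.concatenate([hexes[:, list(f)] for f in HEX_FACES])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return faces[counts[inv] == 1]


def hex_volumes(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """Element volumes via the divergence theorem on triangulated faces."""
    vol = np.zeros(len(hexes))
    for f in HEX_FACES:
        quad = nodes[hexes[:, list(f)]]  # (E, 4, 3)
        for tri in ((0, 1, 2), (0, 2, 3)):
            a, b, c = (quad[:, i] for i in tri)
            vol += np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    return vol


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a, b, c = (nodes[tris[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def leaflet_layers(block: ComponentBlock) -> list[np.ndarray]:
    """Partition a leaflet hex block into its 3 through-thickness layers.

    Layers are identified by walking quad interfaces along the anisotropy
    direction; the builder lays elements out layer-major, which we verify.
    """
    n = len(block.elements)
    if n % 3 != 0:
        raise ValueError("leaflet block does not divide into 3 layers")
    per = n // 3
    layers = [block.elements[i * per:(i + 1) * per] for i in range(3)]
    # adjacent layers must share their full quad interface
    for lo, hi in ((0, 1), (1, 2)):
        top = {tuple(sorted(q)) for q in
               np.concatenate([layers[lo][:, list(HEX_FACES[1])]])}
        bot = {tuple(sorted(q)) for q in
               np.concatenate([layers[hi][:, list(HEX_FACES[0])]])}
        if top != bot:
            raise ValueError("leaflet layers do not share quad interfaces")
    return layers


# ----------------------------------------------------------------------
# legacy ASCII VTK unstructured-grid I/O
# ----------------------------------------------------------------------

def save_vtk(mesh: MultiComponentMesh, path: str) -> None:
    lines = ["# vtk DataFile Version 3.0", "valvemesh multi-component mesh",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(mesh.nodes)} float"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.nodes]
    cells, types, comp_id, aniso = [], [], [], []
    for ci, blk in enumerate(mesh.components):
        vtk_type = VTK_TRIANGLE if blk.kind == "triangle" else VTK_HEXAHEDRON
        for ei, el in enumerate(blk.elements):
            cells.append(f"{len(el)} " + " ".join(str(i) for i in el))
            types.append(vtk_type)
            comp_id.append(ci)
            aniso.append(blk.anisotropy[ei] if blk.anisotropy is not None
                         else np.zeros(3))
    total = sum(int(c.split()[0]) + 1 for c in cells)
    lines.append(f"CELLS {len(cells)} {total}")
    lines += cells
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += [str(t) for t in types]
    lines.append(f"CELL_DATA {len(cells)}")
    lines.append("SCALARS component int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(c) for c in comp_id]
    lines.append("VECTORS anisotropy float")
    lines += [" ".join(f"{v:.9g}" for v in a) for a in aniso]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_vtk(path: str) -> MultiComponentMesh:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(range(len(tokens)))

    def find(prefix: str) -> int:
        for i, line in enumerate(tokens):
            if line.startswith(prefix):
                return i
        raise ValueError(f"missing {prefix} section")

    i = find("POINTS")
    n_pts = int(tokens[i].split()[1])
    nodes = np.array([[float(v) for v in tokens[i + 1 + k].split()]
                      for k in range(n_pts)])
    i = find("CELLS")
    n_cells = int(tokens[i].split()[1])
    conn = [[int(v) for v in tokens[i + 1 + k].split()][1:]
            for k in range(n_cells)]
    i = find("CELL_TYPES")
    types = [int(tokens[i + 1 + k]) for k in range(n_cells)]
    i = find("SCALARS component")
    comp_id = [int(tokens[i + 2 + k]) for k in range(n_cells)]
    i = find("VECTORS anisotropy")
    aniso = np.array([[float(v) for v in tokens[i + 1 + k].split()]
                      for k in range(n_cells)])

    blocks = []
    for ci, name in enumerate(COMPONENT_NAMES[:max(comp_id) + 1]):
        idx = [k for k in range(n_cells) if comp_id[k] == ci]
        if not idx:
            continue
        kind = "triangle" if types[idx[0]] == VTK_TRIANGLE else "hexahedron"
        elems = np.array([conn[k] for k in idx])
        an = aniso[idx] if kind == "hexahedron" else None
        if an is not None and np.allclose(an, 0):
            an = None
        blocks.append(ComponentBlock(name, kind, elems, an))
    return MultiComponentMesh(nodes, blocks)


# ----------------------------------------------------------------------
# deterministic sampling for rasterization and chamfer targets
# ----------------------------------------------------------------------

def sample_triangles(nodes: np.ndarray, tris: np.ndarray,
                     per_area: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic surface samples: regular barycentric subdivision.

    Returns points and their area weights.  ``per_area`` is the target
    number of samples per unit area.
    """
    areas = triangle_areas(nodes, tris)
    pts, wts = [], []
    # subdivision level per triangle so that count ~ per_area * area
    n_target = np.maximum(1, np.ceil(areas * per_area)).astype(int)
    levels = np.clip(np.ceil(np.sqrt(n_target)).astype(int), 1, 12)
    for lev in np.unique(levels):
        sel = levels == lev
        tri = tris[sel]
        # barycentric centroids of lev^2 subtriangles
        bary = _subdiv_bary(lev)
        a, b, c = nodes[tri[:, 0]], nodes[tri[:, 1]], nodes[tri[:, 2]]
        p = (bary[:, None, 0, None] * a + bary[:, None, 1, None] * b
             + bary[:, None, 2, None] * c)  # (m, E, 3)
        pts.append(p.reshape(-1, 3))
        w = np.repeat(areas[sel][None, :] / lev**2, len(bary), axis=0)
        wts.append(w.reshape(-1))
    return np.concatenate(pts), np.concatenate(wts)


def _subdiv_bary(level: int) -> np.ndarray:
    """Centroid barycentric coordinates of a level^2 regular subdivision."""
    out = []
    h = 1.0 / level
    for i in range(level):
        for j in range(level - i):
            # upward subtriangle centroid
            out.append(((i + 1 / 3) * h, (j + 1 / 3) * h))
            if j < level - i - 1:
                out.append(((i + 2 / 3) * h, (j + 2 / 3) * h))
    arr = np.array(out)
    return np.column_stack([1 - arr.sum(axis=1), arr[:, 0], arr[:, 1]])


def sample_hexes(nodes: np.ndarray, hexes: np.ndarray,
                 per_volume: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic volume samples: regular m^3 lattice per hexahedron.

    Points are mapped through the trilinear shape functions; each carries a
    volume weight element_volume / m^3.
    """
    vols = np.abs(hex_volumes(nodes, hexes))
    m = np.clip(np.ceil((vols * per_volume) ** (1 / 3)).astype(int), 2, 8)
    pts, wts = [], []
    for mm in np.unique(m):
        sel = m == mm
        corners = nodes[hexes[sel]]  # (E, 8, 3)
        t = (np.arange(mm) + 0.5) / mm
        u, v, w = np.meshgrid(t, t, t, indexing="ij")
        u, v, w = u.ravel(), v.ravel(), w.ravel()
        sh = trilinear_shape(u, v, w)  # (m^3, 8)
        p = np.einsum("mc,ecx->mex", sh, corners)
        pts.append(p.reshape(-1, 3))
        wv = np.repeat(vols[sel][None, :] / mm**3, mm**3, axis=0)
        wts.append(wv.reshape(-1))
    return np.concatenate(pts), np.concatenate(wts)


def trilinear_shape(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Trilinear shape functions in VTK hexahedron corner order."""
    return np.stack([
        (1 - u) * (1 - v) * (1 - w), u * (1 - v) * (1 - w),
        u * v * (1 - w), (1 - u) * v * (1 - w),
        (1 - u) * (1 - v) * w, u * (1 - v) * w,
        u * v * w, (1 - u) * v * w,
    ], axis=1)


def sample_triangle_normals(nodes: np.ndarray, tris: np.ndarray,
                            per_area: float) -> np.ndarray:
    """Outward face normals repeated to match :func:`sample_triangles`."""
    areas = triangle_areas(nodes, tris)
    a, b, c = (nodes[tris[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    n_target = np.maximum(1, np.ceil(areas * per_area)).astype(int)
    levels = np.clip(np.ceil(np.sqrt(n_target)).astype(int), 1, 12)
    out = []
    for lev in np.unique(levels):
        sel = levels == lev
        m = len(_subdiv_bary(lev))
        out.append(np.repeat(n[sel][None], m, axis=0).reshape(-1, 3))
    return np.concatenate(out)


def sample_component_surface(mesh: MultiComponentMesh, name: str,
                             n_points: int = 2000,
                             return_normals: bool = False):
    """About ``n_points`` deterministic samples on a component's surface."""
    tris = mesh.surface_faces(name)
    area = triangle_areas(mesh.nodes, tris).sum()
    pts, _ = sample_triangles(mesh.nodes, tris, per_area=n_points / area)
    if not return_normals:
        return pts
    return pts, sample_triangle_normals(mesh.nodes, tris,
                                        per_area=n_points / area)
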