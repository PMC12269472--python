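"""Toy cortical meshes: construction, validation, distances and text I/O.

The pipeline operates on source-space data defined on a triangulated surface.
Real analyses use FreeSurfer cortical surfaces down-sampled to ~15k sources;
the synthetic experiments here use small icospheres (a closed surface with
near-uniform vertex spacing) or planar grids (convenient for checking the
Gaussian smoothing kernel on regular spacing). Coordinates are in mm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

__all__ = [
    "CorticalMesh",
    "build_mesh",
    "icosphere_mesh",
    "grid_mesh",
    "read_mesh",
    "write_mesh",
    "read_freesurfer_surface",
]


@dataclass(frozen=True)
class CorticalMesh:
    """A triangulated surface carrying per-vertex positions in mm.

    Vertex indexing is 0-based everywhere in this package.
    """

    vertex_coords: np.ndarray  # (n_vertices, 3) float64, mm
    triangles: np.ndarray      # (n_triangles, 3) int

    def __post_init__(self):
        coords = np.asarray(self.vertex_coords, dtype=float)
        tris = np.asarray(self.triangles, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("vertex_coords must be (n_vertices, 3)")
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise ValueError("triangles must be (n_triangles, 3)")
        if coords.shape[0] < 4:
            raise ValueError(
                f"degenerate mesh: {coords.shape[0]} vertices (< 4)"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("vertex coordinates must be finite")
        if tris.min(initial=0) < 0 or tris.max(initial=-1) >= coords.shape[0]:
            raise ValueError("triangle indices out of range")
        object.__setattr__(self, "vertex_coords", coords)
        object.__setattr__(self, "triangles", tris)
        if not self.is_connected():
            raise ValueError("mesh is not a single connected component")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (n_edges, 2) sorted-index array."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_triangle_counts(self) -> np.ndarray:
        """How many triangles share each unique edge (2 on a closed surface)."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return counts

    def is_connected(self) -> bool:
        e = self.edges()
        n = self.n_vertices
        data = np.ones(len(e))
        adj = coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1

    def vertex_distances(self) -> np.ndarray:
        """Dense Euclidean inter-vertex distance matrix in mm."""
        return cdist(self.vertex_coords, self.vertex_coords)

    def surface_area(self) -> float:
        """Total triangulated surface area in mm^2."""
        p = self.vertex_coords[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def icosphere_mesh(subdivisions: int = 2, radius: float = 70.0) -> CorticalMesh:
    """Icosphere with 10*4**subdivisions + 2 vertices; deterministic."""
    import trimesh

    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return CorticalMesh(np.asarray(m.vertices, float), np.asarray(m.faces, int))


def grid_mesh(nx: int, ny: int, spacing: float = 2.0) -> CorticalMesh:
    """Planar regular triangulated grid (nx*ny vertices), z = 0."""
    if nx < 2 or ny < 2:
        raise ValueError("grid must be at least 2x2")
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    coords = np.column_stack(
        [xs.ravel() * spacing, ys.ravel() * spacing, np.zeros(nx * ny)]
    )
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = v00 + 1
            v10 = v00 + ny
            v11 = v10 + 1
            tris.append([v00, v10, v01])
            tris.append([v01, v10, v11])
    return CorticalMesh(coords, np.asarray(tris, int))


def build_mesh(mesh_spec: dict) -> CorticalMesh:
    """Build a mesh from a specification dict.

    Supported kinds::

        {"kind": "icosphere", "subdivisions": 2, "radius": 70.0}
        {"kind": "grid", "nx": 15, "ny": 20, "spacing": 2.0}

    Deterministic for a fixed spec.
    """
    spec = dict(mesh_spec)
    kind = spec.pop("kind", None)
    if kind == "icosphere":
        return icosphere_mesh(
            subdivisions=int(spec.get("subdivisions", 2)),
            radius=float(spec.get("radius", 70.0)),
        )
    if kind == "grid":
        return grid_mesh(
            nx=int(spec["nx"]), ny=int(spec["ny"]),
            spacing=float(spec.get("spacing", 2.0)),
        )
    raise ValueError(f"unknown mesh kind: {kind!r}")


# --------------------------------------------------------------------------
# Text format: two sections (vertex table, triangle table), 0-based indices.

_HEADER = "# megpac-rsn mesh v1; coordinates in mm; 0-based vertex indexing"


def write_mesh(path: str | Path, mesh: CorticalMesh) -> None:
    buf = io.StringIO()
    buf.write(_HEADER + "\n")
    buf.write(f"vertices {mesh.n_vertices}\n")
    for x, y, z in mesh.vertex_coords:
        buf.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
    buf.write(f"triangles {mesh.n_triangles}\n")
    for a, b, c in mesh.triangles:
        buf.write(f"{a} {b} {c}\n")
    Path(path).write_text(buf.getvalue())


def read_mesh(path: str | Path) -> CorticalMesh:
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    tag, nv = lines[0].split()
    if tag != "vertices":
        raise ValueError(f"{path}: expected 'vertices <n>' header, got {lines[0]!r}")
    nv = int(nv)
    coords = np.array([[float(v) for v in ln.split()] for ln in lines[1:1 + nv]])
    tag, nt = lines[1 + nv].split()
    if tag != "triangles":
        raise ValueError(f"{path}: expected 'triangles <n>' header")
    nt = int(nt)
    tris = np.array(
        [[int(v) for v in ln.split()] for ln in lines[2 + nv:2 + nv + nt]], int
    )
    return CorticalMesh(coords, tris)


def read_freesurfer_surface(path: str | Path) -> CorticalMesh:
    """Import a FreeSurfer binary surface (e.g. lh.pial) as a CorticalMesh."""
    import nibabel.freesurfer as fsio

    coords, faces = fsio.read_geometry(str(path))
    return CorticalMesh(np.asarray(coords, float), np.asarray(faces, int))
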