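"""Mesh data model, I/O, topological connectivity and vertex normals.

The mesh substrate every other stage consumes: a triangle surface mesh of a
single plant with coordinates in millimetres and a known "up" direction.
Meshes coming from multi-view reconstruction may contain holes and several
connected components (floating organs); nothing here assumes watertightness
or manifoldness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components as _sp_components

# organ codes used in per-vertex label arrays
UNASSIGNED = -1
STEM = 0
PETIOLE = 1
LEAF = 2

# leaf sub-label codes
SIDE_UNDEFINED = -1
SIDE_LEFT = 0
SIDE_RIGHT = 1
SURFACE_UNDEFINED = -1
SURFACE_ADAXIAL = 0
SURFACE_ABAXIAL = 1

ORGAN_NAMES = {UNASSIGNED: "unassigned", STEM: "stem", PETIOLE: "petiole", LEAF: "leaf"}
SIDE_NAMES = {SIDE_UNDEFINED: "", SIDE_LEFT: "left", SIDE_RIGHT: "right"}
SURFACE_NAMES = {SURFACE_UNDEFINED: "", SURFACE_ADAXIAL: "adaxial", SURFACE_ABAXIAL: "abaxial"}


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be interpreted as a triangle mesh."""


@dataclass
class PlantMesh:
    """Triangle surface mesh of one plant at one time-point.

    vertices : (n, 3) float array, millimetres
    triangles : (m, 3) int array of vertex indices
    up_vector : unit 3-vector of the world up direction (default +Z)
    """

    vertices: np.ndarray
    triangles: np.ndarray
    up_vector: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.up_vector = np.asarray(self.up_vector, dtype=np.float64)
        n = self.up_vector
        self.up_vector = n / np.linalg.norm(n)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                bad = np.where(
                    (self.triangles.min(axis=1) < 0)
                    | (self.triangles.max(axis=1) >= len(self.vertices))
                )[0][0]
                raise MeshFormatError(
                    f"face {bad} references vertex {self.triangles[bad].max()} "
                    f"but the mesh has only {len(self.vertices)} vertices"
                )
            degenerate = (
                (self.triangles[:, 0] == self.triangles[:, 1])
                | (self.triangles[:, 1] == self.triangles[:, 2])
                | (self.triangles[:, 0] == self.triangles[:, 2])
            )
            if degenerate.any():
                self.triangles = self.triangles[~degenerate]
        self._normals: np.ndarray | None = None
        self._normal_defined: np.ndarray | None = None
        self._adjacency: csr_matrix | None = None

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit normal and area of every triangle (zero normal if degenerate)."""
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        area = 0.5 * norm
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(norm[:, None] > 1e-12, cross / np.maximum(norm, 1e-300)[:, None], 0.0)
        return unit, area

    @property
    def vertex_normals(self) -> np.ndarray:
        if self._normals is None:
            self._normals, self._normal_defined = vertex_normals(self, return_mask=True)
        return self._normals

    @property
    def normal_defined(self) -> np.ndarray:
        if self._normal_defined is None:
            _ = self.vertex_normals
        return self._normal_defined

    @property
    def adjacency(self) -> csr_matrix:
        """Sparse symmetric vertex adjacency (shared triangle edge)."""
        if self._adjacency is None:
            self._adjacency = adjacency_matrix(self)
        return self._adjacency

    def edge_graph(self) -> csr_matrix:
        """Adjacency weighted by Euclidean edge length (for surface paths)."""
        a = self.adjacency.tocoo()
        w = np.linalg.norm(self.vertices[a.row] - self.vertices[a.col], axis=1)
        return coo_matrix((w, (a.row, a.col)), shape=a.shape).tocsr()

    def copy(self) -> "PlantMesh":
        return PlantMesh(self.vertices.copy(), self.triangles.copy(), self.up_vector.copy())

    def transformed(self, rotation: np.ndarray | None = None, translation=0.0) -> "PlantMesh":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation).T
        v = v + translation
        return PlantMesh(v, self.triangles.copy(), self.up_vector.copy())


@dataclass
class Curve3D:
    """Ordered polyline in 3-space with arc-length parameterisation."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("a curve needs at least two control points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arc_length(self) -> float:
        return float(self._cum[-1])

    def evaluate(self, t) -> np.ndarray:
        """Points at normalised arc-length parameters t in [0, 1]; (k, 3)."""
        t = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), 0.0, 1.0)
        s = t * self.arc_length
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self.points) - 2)
        seg_len = np.maximum(self._cum[idx + 1] - self._cum[idx], 1e-300)
        frac = (s - self._cum[idx]) / seg_len
        return self.points[idx] + frac[:, None] * (self.points[idx + 1] - self.points[idx])

    def point_at(self, t: float) -> np.ndarray:
        return self.evaluate([t])[0]

    def nearest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distance from each query point to the polyline and the parameter t
        of the closest point (vectorised over all segments)."""
        q = np.asarray(points, dtype=float).reshape(-1, 3)
        a = self.points[:-1]
        d = self.points[1:] - a
        dd = np.einsum("ij,ij->i", d, d)
        dd = np.maximum(dd, 1e-300)
        # (nq, nseg) projection parameters
        tseg = (np.einsum("qj,sj->qs", q, d) - np.einsum("sj,sj->s", a, d)) / dd
        tseg = np.clip(tseg, 0.0, 1.0)
        closest = a[None, :, :] + tseg[:, :, None] * d[None, :, :]
        dist = np.linalg.norm(q[:, None, :] - closest, axis=2)
        best = np.argmin(dist, axis=1)
        rows = np.arange(len(q))
        s_along = self._cum[best] + tseg[rows, best] * np.sqrt(dd[best])
        return dist[rows, best], s_along / max(self.arc_length, 1e-300)


@dataclass
class SegmentationLabels:
    """Per-vertex organ assignment.

    organ : (n,) int — STEM / PETIOLE / LEAF / UNASSIGNED
    index : (n,) int — internode index for stem vertices (0 = base),
            organ index for petiole/leaf vertices
    side : (n,) int — LEFT/RIGHT, leaf vertices only
    surface : (n,) int — ADAXIAL/ABAXIAL, leaf vertices only
    """

    organ: np.ndarray
    index: np.ndarray
    side: np.ndarray
    surface: np.ndarray

    @classmethod
    def empty(cls, n: int) -> "SegmentationLabels":
        return cls(
            organ=np.full(n, UNASSIGNED, dtype=np.int64),
            index=np.full(n, -1, dtype=np.int64),
            side=np.full(n, SIDE_UNDEFINED, dtype=np.int64),
            surface=np.full(n, SURFACE_UNDEFINED, dtype=np.int64),
        )

    def __len__(self) -> int:
        return len(self.organ)

    @property
    def leaf_indices(self) -> np.ndarray:
        return np.unique(self.index[self.organ == LEAF])

    @property
    def petiole_indices(self) -> np.ndarray:
        return np.unique(self.index[self.organ == PETIOLE])

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    @property
    def n_internodes(self) -> int:
        stem = self.organ == STEM
        return len(np.unique(self.index[stem])) if stem.any() else 0

    def leaf_mask(self, i: int) -> np.ndarray:
        return (self.organ == LEAF) & (self.index == i)

    def petiole_mask(self, i: int) -> np.ndarray:
        return (self.organ == PETIOLE) & (self.index == i)

    def copy(self) -> "SegmentationLabels":
        return SegmentationLabels(
            self.organ.copy(), self.index.copy(), self.side.copy(), self.surface.copy()
        )

    def subset(self, keep: np.ndarray) -> "SegmentationLabels":
        return SegmentationLabels(
            self.organ[keep], self.index[keep], self.side[keep], self.surface[keep]
        )

    # ------------------------------------------------------------------
    def to_table(self) -> np.ndarray:
        return np.column_stack([self.organ, self.index, self.side, self.surface])

    def save_csv(self, path) -> None:
        """Integer label table plus a JSON legend alongside."""
        path = Path(path)
        header = "organ,index,side,surface"
        np.savetxt(path, self.to_table(), fmt="%d", delimiter=",", header=header, comments="")
        legend = {
            "organ": {str(k): v for k, v in ORGAN_NAMES.items()},
            "side": {str(k): v for k, v in SIDE_NAMES.items()},
            "surface": {str(k): v for k, v in SURFACE_NAMES.items()},
        }
        path.with_suffix(".legend.json").write_text(json.dumps(legend, indent=1))

    @classmethod
    def load_csv(cls, path) -> "SegmentationLabels":
        table = np.loadtxt(path, dtype=np.int64, delimiter=",", skiprows=1, ndmin=2)
        return cls(table[:, 0], table[:, 1], table[:, 2], table[:, 3])


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def load_mesh(path, format: str = "auto", scale: float = 1.0, up=(0.0, 0.0, 1.0)) -> PlantMesh:
    """Read an OBJ or PLY triangle mesh.

    Coordinates are taken as millimetres (``scale`` applies a uniform factor
    at load). Non-triangular faces are triangulated by a fan from the first
    face vertex; unreferenced vertices are retained. Vertex order is
    preserved exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    file_type = None if format == "auto" else format.lower()
    try:
        m = trimesh.load_mesh(str(path), file_type=file_type, process=False, maintain_order=True)
    except IndexError as exc:  # out-of-range face index inside the loader
        raise MeshFormatError(f"{path}: a face references a nonexistent vertex ({exc})") from exc
    if isinstance(m, trimesh.Scene):
        geoms = list(m.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: no geometry found")
        m = trimesh.util.concatenate(geoms)
    vertices = np.asarray(m.vertices, dtype=np.float64) * float(scale)
    faces = np.asarray(m.faces, dtype=np.int64)
    return PlantMesh(vertices, faces, up_vector=np.asarray(up, dtype=float))


def save_mesh(mesh: PlantMesh, path, vertex_colors: np.ndarray | None = None) -> None:
    """Write OBJ or PLY (by extension). PLY may carry per-vertex colours."""
    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    if vertex_colors is not None:
        tm.visual.vertex_colors = vertex_colors
    tm.export(str(path))


def labels_to_colors(labels: SegmentationLabels, seed: int = 0) -> np.ndarray:
    """Deterministic RGBA colour per (organ, index) pair, for visual checks."""
    rng = np.random.default_rng(seed)
    keys = labels.organ * 1000 + labels.index
    uniq, inv = np.unique(keys, return_inverse=True)
    palette = (rng.uniform(40, 255, size=(len(uniq), 3))).astype(np.uint8)
    rgba = np.concatenate([palette[inv], np.full((len(inv), 1), 255, np.uint8)], axis=1)
    return rgba


# ----------------------------------------------------------------------
# connectivity and normals
# ----------------------------------------------------------------------

def adjacency_matrix(mesh: PlantMesh) -> csr_matrix:
    n = mesh.n_vertices
    if mesh.n_triangles == 0:
        return csr_matrix((n, n))
    t = mesh.triangles
    rows = np.concatenate([t[:, 0], t[:, 1], t[:, 1], t[:, 2], t[:, 2], t[:, 0]])
    cols = np.concatenate([t[:, 1], t[:, 0], t[:, 2], t[:, 1], t[:, 0], t[:, 2]])
    data = np.ones(len(rows), dtype=np.int8)
    a = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    a.data[:] = 1
    return a


def vertex_adjacency(mesh: PlantMesh) -> list[np.ndarray]:
    """Neighbour index list per vertex. Two vertices are neighbours iff they
    share a triangle edge; isolated vertices get an empty list."""
    a = mesh.adjacency
    return [a.indices[a.indptr[i]: a.indptr[i + 1]] for i in range(mesh.n_vertices)]


def vertex_normals(mesh: PlantMesh, return_mask: bool = False):
    """Per-vertex unit normal: the normalised mean of the unit normals of the
    incident non-degenerate triangles. Vertices with no such triangle have an
    undefined normal (zero vector, mask False)."""
    n = mesh.n_vertices
    normals = np.zeros((n, 3))
    counts = np.zeros(n)
    if mesh.n_triangles:
        tn, area = mesh.triangle_normals_areas()
        ok = area > 1e-12
        tri = mesh.triangles[ok]
        tn = tn[ok]
        for k in range(3):
            np.add.at(normals, tri[:, k], tn)
            np.add.at(counts, tri[:, k], 1.0)
    defined = counts > 0
    norm = np.linalg.norm(normals, axis=1)
    # a vertex whose incident normals cancel exactly is also undefined
    defined &= norm > 1e-12
    normals[defined] /= norm[defined][:, None]
    normals[~defined] = 0.0
    if return_mask:
        return normals, defined
    return normals


def connected_components(mesh: PlantMesh) -> np.ndarray:
    """Component id per vertex; two vertices share an id iff a topological
    path connects them. Empty mesh gives an empty array."""
    if mesh.n_vertices == 0:
        return np.zeros(0, dtype=np.int64)
    _, lab = _sp_components(mesh.adjacency, directed=False)
    return lab.astype(np.int64)
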