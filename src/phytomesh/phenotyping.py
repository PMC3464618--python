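"""Phenotypic parameter extraction from a segmented plant mesh.

Parameters follow the morphological conventions used for dicot phenotyping:

* main stem: height (vertical extent of the stem region), length (arc length
  of the stem curve), inclination (angle between the stem axis and up);
* petiole: length (arc length of a centre-of-mass curve, clipped at the stem
  tube surface) and initiation angle (between the stem axis and the
  base->highest-point vector of that curve);
* leaf blade: width and length as the arc lengths of on-surface curves
  between the extreme points of the sagittal/coronal planes, projected onto
  the opposite plane to discard transversal excursions — this makes both
  measures developed (laid-flat) dimensions, robust to blade bending;
  area (mean of the adaxial and abaxial triangle-area sums), thickness
  (mean adaxial-to-nearest-abaxial vertex distance), and inclination (angle
  between the projected leaf axis and the stem axis).

Undefined measurements are reported as NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from phytomesh import mesh_core as mc
from phytomesh.config import PipelineConfig
from phytomesh.mesh_core import Curve3D, PlantMesh, SegmentationLabels
from phytomesh.segmentation import StemModel, planar_distance


@dataclass
class LeafFrame:
    """Leaf-local reference frame from the sagittal/coronal construction."""

    centroid: np.ndarray
    u1: np.ndarray  # sagittal plane normal (lateral direction, toward RIGHT)
    u2: np.ndarray  # coronal plane normal (centroid -> apex)
    S1: int  # vertex id, extreme on the positive side of the sagittal plane
    S2: int  # vertex id, extreme on the negative side
    C1: int  # vertex id, extreme toward the base
    C2: int  # vertex id, extreme toward the apex


@dataclass
class PhenotypeRecord:
    """All parameters for one plant at one time-point."""

    stem_height: float
    stem_length: float
    stem_inclination: float
    petioles: pd.DataFrame  # index: organ index; columns: length, initiation_angle
    leaves: pd.DataFrame  # index: organ index; columns: width..inclination, flag
    provenance: dict = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (plant, timepoint, organ_type, organ_index,
        parameter, value, flag)."""
        plant = self.provenance.get("mesh_id", "")
        tp = self.provenance.get("timepoint", 0)
        rows = []
        for name, value in (
            ("height", self.stem_height),
            ("length", self.stem_length),
            ("inclination", self.stem_inclination),
        ):
            rows.append((plant, tp, "stem", 0, name, value, ""))
        for i, r in self.petioles.iterrows():
            for name in ("length", "initiation_angle"):
                rows.append((plant, tp, "petiole", i, name, r[name], ""))
        for i, r in self.leaves.iterrows():
            flag = r.get("flag", "")
            for name in ("width", "length", "area", "thickness", "inclination"):
                rows.append((plant, tp, "leaf", i, name, r[name], flag))
        return pd.DataFrame(
            rows,
            columns=["plant", "timepoint", "organ_type", "organ_index",
                     "parameter", "value", "flag"],
        )

    def save_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @staticmethod
    def load_long(path) -> pd.DataFrame:
        return pd.read_csv(path, keep_default_na=True)


# ----------------------------------------------------------------------
# stem and petiole
# ----------------------------------------------------------------------

def stem_metrics(
    mesh: PlantMesh, labels: SegmentationLabels, stem_model: StemModel
) -> tuple[float, float, float]:
    """(height mm, length mm, inclination deg) of the main stem."""
    stem = labels.organ == mc.STEM
    if not stem.any():
        raise ValueError("empty stem region")
    up = mesh.up_vector
    h = mesh.vertices[stem] @ up
    height = float(h.max() - h.min())
    idx = np.where(stem)[0]
    axis = mesh.vertices[idx[np.argmax(h)]] - mesh.vertices[idx[np.argmin(h)]]
    axis = axis / np.linalg.norm(axis)
    inclination = float(np.degrees(np.arccos(np.clip(axis @ up, -1.0, 1.0))))
    return height, float(stem_model.curve.arc_length), inclination


def _center_of_mass_curve(
    mesh: PlantMesh, idx: np.ndarray, start_vertex: int, bin_width: float
) -> Curve3D | None:
    """Curve through local centres of mass, binned by on-surface distance."""
    pos = mesh.vertices[idx]
    sub = mesh.edge_graph()[idx][:, idx]
    start_local = int(np.where(idx == start_vertex)[0][0])
    g = dijkstra(sub, directed=False, indices=start_local)
    finite = np.isfinite(g)
    if finite.sum() < 2:
        return None
    g[~finite] = 0.0
    nb = max(2, int(np.ceil(g.max() / bin_width)))
    bins = np.clip((g / bin_width).astype(int), 0, nb - 1)
    centroids = [pos[bins == b].mean(axis=0) for b in range(nb) if (bins == b).any()]
    if len(centroids) < 2:
        return None
    # anchor the curve at the extreme vertices so binning does not trim the
    # ends by half a bin
    pts = [pos[int(np.argmin(g))]] + centroids + [pos[int(np.argmax(g))]]
    return Curve3D(np.asarray(pts))


def petiole_metrics(
    mesh: PlantMesh,
    labels: SegmentationLabels,
    stem_model: StemModel,
    petiole: int,
    config: PipelineConfig | None = None,
) -> tuple[float, float]:
    """(length mm, initiation angle deg) of one petiole; (nan, nan) if the
    petiole is missing (e.g. detached in the reconstruction)."""
    cfg = config or PipelineConfig()
    mask = labels.petiole_mask(petiole)
    if not mask.any():
        return float("nan"), float("nan")
    idx = np.where(mask)[0]
    d = planar_distance(mesh.vertices[idx], stem_model.curve, mesh.up_vector)
    start = idx[int(np.argmin(d))]
    curve = _center_of_mass_curve(mesh, idx, start, cfg.petiole_bin)
    if curve is None:
        return float("nan"), float("nan")
    pts = curve.points
    # clip the curve at the stem tube surface so the length runs from the
    # stem surface to the blade, matching the external measurement
    dcp = planar_distance(pts, stem_model.curve, mesh.up_vector)
    outside = dcp >= stem_model.radius
    if not outside.any():
        return float("nan"), float("nan")
    first = int(np.argmax(outside))
    if first > 0:
        a, b = pts[first - 1], pts[first]
        da, db = dcp[first - 1], dcp[first]
        frac = (stem_model.radius - da) / max(db - da, 1e-12)
        entry = a + np.clip(frac, 0.0, 1.0) * (b - a)
        pts = np.vstack([entry, pts[first:]])
    else:
        pts = pts[first:]
    if len(pts) < 2:
        return float("nan"), float("nan")
    curve = Curve3D(pts)
    length = curve.arc_length

    up = mesh.up_vector
    heights = pts @ up
    dcp2 = planar_distance(pts, stem_model.curve, up)
    l_i = pts[int(np.argmin(dcp2))]
    near_top = np.where(heights >= heights.max() - 0.5)[0]
    h_i = pts[near_top[int(np.argmax(np.linalg.norm(pts[near_top] - l_i, axis=1)))]]
    vec = h_i - l_i
    if np.linalg.norm(vec) < 1e-9:
        return length, float("nan")
    vec = vec / np.linalg.norm(vec)
    alpha = float(np.degrees(np.arccos(np.clip(vec @ stem_model.axis, -1.0, 1.0))))
    return float(length), alpha


# ----------------------------------------------------------------------
# leaf blade
# ----------------------------------------------------------------------

def leaf_frame(
    mesh: PlantMesh, labels: SegmentationLabels, leaf: int, stem_model: StemModel
) -> LeafFrame:
    """Sagittal/coronal frame and the four extreme points of one blade."""
    mask = labels.leaf_mask(leaf)
    idx = np.where(mask)[0]
    if len(idx) == 0:
        raise ValueError(f"leaf {leaf} is empty")
    side = labels.side[idx]
    right = idx[side == mc.SIDE_RIGHT]
    left = idx[side == mc.SIDE_LEFT]
    if len(right) == 0 or len(left) == 0:
        raise ValueError(f"leaf {leaf}: degenerate sagittal split (one side empty)")
    pts = mesh.vertices[idx]
    centroid = pts.mean(axis=0)
    u1 = (mesh.vertices[right] - centroid).mean(axis=0)
    n1 = np.linalg.norm(u1)
    if n1 < 1e-9:
        raise ValueError(f"leaf {leaf}: right-side mean vector vanished")
    u1 = u1 / n1
    _, t = stem_model.curve.nearest(centroid[None, :])
    ref = stem_model.curve.evaluate(t)[0]
    apex_local = int(np.argmax(np.linalg.norm(pts - ref, axis=1)))
    u2 = pts[apex_local] - centroid
    n2 = np.linalg.norm(u2)
    if n2 < 1e-9:
        raise ValueError(f"leaf {leaf}: apex coincides with the centroid")
    u2 = u2 / n2
    s = (pts - centroid) @ u1
    c = (pts - centroid) @ u2
    if s.max() <= 0 or s.min() >= 0:
        raise ValueError(f"leaf {leaf}: all vertices on one side of the sagittal plane")
    return LeafFrame(
        centroid=centroid,
        u1=u1,
        u2=u2,
        S1=int(idx[np.argmax(s)]),
        S2=int(idx[np.argmin(s)]),
        C1=int(idx[np.argmin(c)]),
        C2=int(idx[np.argmax(c)]),
    )


def _surface_path(mesh: PlantMesh, idx: np.ndarray, a: int, b: int) -> np.ndarray | None:
    """Shortest on-surface polyline between two vertices of a region."""
    sub = mesh.edge_graph()[idx][:, idx]
    local = {v: k for k, v in enumerate(idx)}
    ia, ib = local[a], local[b]
    dist, pred = dijkstra(sub, directed=False, indices=ia, return_predecessors=True)
    if not np.isfinite(dist[ib]):
        return None
    chain = [ib]
    while chain[-1] != ia:
        p = pred[chain[-1]]
        if p < 0:
            return None
        chain.append(int(p))
    return mesh.vertices[idx[np.asarray(chain[::-1])]]


def _projected_arclength(path: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> float:
    q = path - np.outer((path - origin) @ normal, normal)
    return float(np.linalg.norm(np.diff(q, axis=0), axis=1).sum())


def leaf_width_length(
    mesh: PlantMesh, labels: SegmentationLabels, leaf: int, frame: LeafFrame
) -> tuple[float, float, str]:
    """(width mm, length mm, flag).

    Width: arc length of the on-surface path S1->S2 projected onto the
    coronal plane; length: path C1->C2 projected onto the sagittal plane.
    If a hole disconnects the endpoints the straight segment is used and the
    returned flag says so.
    """
    idx = np.where(labels.leaf_mask(leaf))[0]
    flag = ""
    path_w = _surface_path(mesh, idx, frame.S1, frame.S2)
    if path_w is None:
        path_w = mesh.vertices[[frame.S1, frame.S2]]
        flag = "width_straight_fallback"
    width = _projected_arclength(path_w, frame.centroid, frame.u2)
    path_l = _surface_path(mesh, idx, frame.C1, frame.C2)
    if path_l is None:
        path_l = mesh.vertices[[frame.C1, frame.C2]]
        flag = (flag + ";" if flag else "") + "length_straight_fallback"
    length = _projected_arclength(path_l, frame.centroid, frame.u1)
    return width, length, flag


def leaf_area(mesh: PlantMesh, labels: SegmentationLabels, leaf: int) -> tuple[float, bool]:
    """Mean of adaxial and abaxial triangle-area sums; (area, two_sided).

    Triangles are assigned to a surface by the majority of their vertices;
    a single-surface (open sheet) leaf returns that surface's sum alone.
    """
    mask = labels.leaf_mask(leaf)
    in_leaf = mask[mesh.triangles].sum(axis=1) >= 2
    if not in_leaf.any():
        return float("nan"), False
    _, areas = mesh.triangle_normals_areas()
    tris = mesh.triangles[in_leaf]
    tri_areas = areas[in_leaf]
    surf = labels.surface[tris]
    surf = np.where(mask[tris], surf, mc.SURFACE_UNDEFINED)
    ad_votes = (surf == mc.SURFACE_ADAXIAL).sum(axis=1)
    ab_votes = (surf == mc.SURFACE_ABAXIAL).sum(axis=1)
    area_ad = float(tri_areas[ad_votes >= ab_votes].sum())
    area_ab = float(tri_areas[ab_votes > ad_votes].sum())
    if area_ad == 0.0 or area_ab == 0.0:
        return max(area_ad, area_ab), False
    return 0.5 * (area_ad + area_ab), True


def leaf_thickness(mesh: PlantMesh, labels: SegmentationLabels, leaf: int) -> float:
    """Mean adaxial-vertex to nearest-abaxial-vertex distance; NaN if the
    blade is a single open sheet."""
    mask = labels.leaf_mask(leaf)
    ad = mask & (labels.surface == mc.SURFACE_ADAXIAL)
    ab = mask & (labels.surface == mc.SURFACE_ABAXIAL)
    if not ad.any() or not ab.any():
        return float("nan")
    tree = cKDTree(mesh.vertices[ab])
    d, _ = tree.query(mesh.vertices[ad])
    return float(d.mean())


def leaf_inclination(frame: LeafFrame, stem_axis: np.ndarray, mesh: PlantMesh) -> float:
    """Angle (deg, [0, 180]) between the projected leaf axis and the stem axis.

    The leaf axis is the C1->C2 vector projected onto the sagittal plane.
    """
    v = mesh.vertices[frame.C2] - mesh.vertices[frame.C1]
    v = v - (v @ frame.u1) * frame.u1
    n = np.linalg.norm(v)
    if n < 1e-9:
        return float("nan")
    v = v / n
    return float(np.degrees(np.arccos(np.clip(v @ stem_axis, -1.0, 1.0))))


# ----------------------------------------------------------------------
# assembly
# ----------------------------------------------------------------------

def extract_phenotypes(
    mesh: PlantMesh,
    labels: SegmentationLabels,
    stem_model: StemModel,
    config: PipelineConfig | None = None,
    mesh_id: str = "",
    timepoint: int = 0,
) -> PhenotypeRecord:
    """Measure every parameter on a segmented mesh; NaN where undefined."""
    cfg = config or PipelineConfig()
    height, length, incl = stem_metrics(mesh, labels, stem_model)
    leaf_ids = labels.leaf_indices
    organ_ids = sorted(set(leaf_ids) | set(labels.petiole_indices))

    pet_rows = []
    for i in organ_ids:
        plen, pang = petiole_metrics(mesh, labels, stem_model, i, cfg)
        pet_rows.append(dict(organ=i, length=plen, initiation_angle=pang))
    leaf_rows = []
    for i in leaf_ids:
        row = dict(organ=i, width=np.nan, length=np.nan, area=np.nan,
                   thickness=np.nan, inclination=np.nan, flag="")
        try:
            frame = leaf_frame(mesh, labels, i, stem_model)
        except ValueError as exc:
            row["flag"] = f"unmeasurable:{exc}"
            leaf_rows.append(row)
            continue
        w, ln, flag = leaf_width_length(mesh, labels, i, frame)
        area, two_sided = leaf_area(mesh, labels, i)
        row.update(
            width=w,
            length=ln,
            area=area,
            thickness=leaf_thickness(mesh, labels, i),
            inclination=leaf_inclination(frame, stem_model.axis, mesh),
            flag=flag if two_sided else (flag + ";" if flag else "") + "single_surface",
        )
        leaf_rows.append(row)

    petioles = pd.DataFrame(pet_rows).set_index("organ") if pet_rows else \
        pd.DataFrame(columns=["length", "initiation_angle"])
    leaves = pd.DataFrame(leaf_rows).set_index("organ") if leaf_rows else \
        pd.DataFrame(columns=["width", "length", "area", "thickness", "inclination", "flag"])
    return PhenotypeRecord(
        stem_height=height,
        stem_length=length,
        stem_inclination=incl,
        petioles=petioles,
        leaves=leaves,
        provenance=dict(mesh_id=mesh_id, timepoint=timepoint, config_hash=cfg.hash()),
    )
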