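"""Four-stage hybrid morphological segmentation of a plant mesh.

1. Coarse partition: a curve is fitted to the main stem, everything within a
   planar radius of it becomes the stem region M, and the remaining vertices
   are grown into regions N_i over topological neighbours (floating pieces
   seed their own region, which makes the stage robust to holes and detached
   parts).
2. Stem refinement: a tube is fitted around the stem curve; vertices inside
   the tube are stem, vertices bordering it mark the petiole junctions that
   partition the stem into internodes.
3. Petiole separation: a curve through local centres of mass follows each
   attached region from the stem into the blade; a thin tube around it
   separates petiole from blade.
4. Leaf stage: oversized regions (two leaves fused by the reconstruction)
   are split by a plane through the farthest-apart vertex pair; each blade is
   then split sagittally (left/right, by angle sign in the plane normal to
   the stem axis) and transversally (adaxial/abaxial, by iterative normal
   clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.sparse.csgraph import connected_components as _sp_components
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, QhullError, cKDTree

from phytomesh import mesh_core as mc
from phytomesh.config import PipelineConfig
from phytomesh.mesh_core import Curve3D, PlantMesh, SegmentationLabels


class StemNotFoundError(RuntimeError):
    """The mesh contains no detectable main stem."""


@dataclass
class TubeFit:
    axis: Curve3D
    radius: float
    inliers: np.ndarray  # bool mask over the input points
    residual: float  # mean |point-to-surface| distance over inliers, mm


@dataclass
class StemModel:
    curve: Curve3D
    axis: np.ndarray  # unit vector, lowest -> highest stem vertex
    radius: float
    junction_heights: np.ndarray  # normalised heights in [0, 1], sorted
    base_point: np.ndarray  # lowest stem vertex

    @property
    def internode_intervals(self) -> list[tuple[float, float]]:
        bounds = np.concatenate([[0.0], self.junction_heights, [1.0]])
        return [(float(a), float(b)) for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class SegmentationResult:
    labels: SegmentationLabels
    stem_model: StemModel
    n_coarse_regions: int
    diagnostics: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------

def _planar_offsets(points: np.ndarray, curve: Curve3D, up: np.ndarray) -> np.ndarray:
    """Offset from each point to its nearest curve point, with the up
    component removed (a 'planar radius' around the stem curve)."""
    _, t = curve.nearest(points)
    cp = curve.evaluate(t)
    delta = points - cp
    return delta - np.outer(delta @ up, up)


def planar_distance(points: np.ndarray, curve: Curve3D, up: np.ndarray) -> np.ndarray:
    return np.linalg.norm(_planar_offsets(points, curve, up), axis=1)


# ----------------------------------------------------------------------
# step 1: stem curve + coarse partition
# ----------------------------------------------------------------------

def fit_stem_curve(mesh: PlantMesh, config: PipelineConfig | None = None) -> Curve3D:
    """Fit the main-stem curve c_p from one extremity to the other.

    The mesh is sliced into horizontal bins; the lowest slice's densest
    planar cluster (mode of a 2D histogram) anchors the curve, which is then
    walked upward slice by slice, each new centre taken as the centroid of
    the vertices inside a planar window around the previous centre. A
    smoothing spline through the chain gives the final curve.
    """
    cfg = config or PipelineConfig()
    up = mesh.up_vector
    v = mesh.vertices
    if len(v) < 10:
        raise StemNotFoundError("no stem found: too few vertices")
    h = v @ up
    e1, e2 = _frame_perp(up)
    xy = np.column_stack([v @ e1, v @ e2])
    hmin, hmax = float(h.min()), float(h.max())
    if hmax - hmin < cfg.min_stem_span:
        raise StemNotFoundError("no stem found: vertical extent too small")
    edges = np.linspace(hmin, hmax, cfg.n_height_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, h, side="right") - 1, 0, cfg.n_height_bins - 1)

    centers: list[np.ndarray] = []
    heights: list[float] = []
    member_dists: list[np.ndarray] = []
    prev_xy = None
    misses = 0
    for b in range(cfg.n_height_bins):
        idx = np.where(bin_of == b)[0]
        if len(idx) < cfg.min_bin_count:
            if prev_xy is not None:
                misses += 1
                if misses > 1:
                    break
            continue
        if prev_xy is None:
            cand_xy = _histogram_mode(xy[idx], cfg.hist_cell)
        else:
            cand_xy = prev_xy
        sel = idx
        for _ in range(3):  # recentre inside the planar window
            d = np.linalg.norm(xy[idx] - cand_xy, axis=1)
            sel = idx[d <= cfg.walk_window]
            if len(sel) < cfg.min_bin_count:
                break
            cand_xy = xy[sel].mean(axis=0)
        # the accepted cluster must stay tube-like: a flat organ wandering
        # over the stem apex fills the window instead of forming a ring
        tube_like = (
            len(sel) >= cfg.min_bin_count
            and float(np.median(np.linalg.norm(xy[sel] - cand_xy, axis=1)))
            <= 0.5 * cfg.max_stem_radius
        )
        if not tube_like:
            if prev_xy is not None:
                misses += 1
                if misses > 1:
                    break
            continue
        misses = 0
        prev_xy = cand_xy
        centers.append(np.concatenate([cand_xy, [float(h[sel].mean())]]))
        heights.append(float(h[sel].mean()))
        member_dists.append(np.linalg.norm(xy[sel] - cand_xy, axis=1))

    if len(centers) < cfg.min_stem_bins:
        raise StemNotFoundError("no stem found: too few valid slices")
    span = heights[-1] - heights[0]
    if span < cfg.min_stem_span:
        raise StemNotFoundError("no stem found: chain too short")
    r_est = float(np.median(np.concatenate(member_dists)))
    if r_est > cfg.max_stem_radius:
        raise StemNotFoundError(
            f"no stem found: densest cluster spread {r_est:.1f} mm is not tubular"
        )

    centers = np.asarray(centers)
    hs = centers[:, 2]
    order = np.argsort(hs)
    hs, cxy = hs[order], centers[order, :2]

    def fit_spline(hh, cc, smooth):
        h_d = np.linspace(hh[0], hh[-1], 100)
        if len(hh) > 4:
            sx = UnivariateSpline(hh, cc[:, 0], k=3, s=smooth)
            sy = UnivariateSpline(hh, cc[:, 1], k=3, s=smooth)
            return h_d, np.column_stack([sx(h_d), sy(h_d)])
        return h_d, np.column_stack([
            np.interp(h_d, hh, cc[:, 0]), np.interp(h_d, hh, cc[:, 1])
        ])

    h_dense, xy_dense = fit_spline(hs, cxy, len(hs) * 2.0)

    # robust near-straight reference axis: iteratively reweighted linear fit
    # of the walk centres over height, rejecting bins contaminated by organ
    # mass passing close to the stem
    acc = np.ones(len(hs), dtype=bool)
    coef = None
    for _ in range(4):
        if acc.sum() < 3:
            break
        A = np.column_stack([np.ones(acc.sum()), hs[acc]])
        coef, *_ = np.linalg.lstsq(A, cxy[acc], rcond=None)
        res = np.linalg.norm(cxy - np.column_stack([np.ones(len(hs)), hs]) @ coef, axis=1)
        mad = float(np.median(np.abs(res[acc] - np.median(res[acc]))))
        acc = res <= max(np.median(res[acc]) + 2.5 * 1.4826 * mad, 1.0)
    if coef is not None:
        line_xy = np.column_stack([np.ones(len(h_dense)), h_dense]) @ coef

        # re-select tube-ring vertices per bin around the reference line,
        # drop the radial outliers (petiole stubs, blade bases), and refit
        hh, cc = [], []
        for b in range(cfg.n_height_bins):
            idx = np.where(bin_of == b)[0]
            if len(idx) < cfg.min_bin_count:
                continue
            hb = float(h[idx].mean())
            if hb < h_dense[0] - 1e-9 or hb > h_dense[-1] + 1e-9:
                continue
            c = np.array([1.0, hb]) @ coef
            d = np.linalg.norm(xy[idx] - c, axis=1)
            sel = idx[d <= 0.75 * cfg.walk_window]
            if len(sel) < cfg.min_bin_count:
                continue
            d = np.linalg.norm(xy[sel] - c, axis=1)
            r_b = float(np.median(d))
            band = max(2.5 * 1.4826 * float(np.median(np.abs(d - r_b))), 0.6)
            ring = sel[np.abs(d - r_b) <= band]
            if len(ring) >= cfg.min_bin_count:
                hh.append(float(h[ring].mean()))
                cc.append(xy[ring].mean(axis=0))
        if len(hh) >= cfg.min_stem_bins:
            h_dense, xy_dense = fit_spline(np.asarray(hh), np.asarray(cc), len(hh) * 0.5)
    # extend to the true vertical extremes of the stem cluster
    pts = xy_dense[:, 0][:, None] * e1 + xy_dense[:, 1][:, None] * e2 + h_dense[:, None] * up
    # linear end extension so the curve spans the full stem extent
    near0 = np.linalg.norm(xy - xy_dense[0], axis=1) <= cfg.walk_window
    near1 = np.linalg.norm(xy - xy_dense[-1], axis=1) <= cfg.walk_window
    h_lo = float(h[near0].min()) if near0.any() else h_dense[0]
    h_hi = float(h[near1].max()) if near1.any() else h_dense[-1]
    ext = []
    k = min(15, len(pts) - 1)
    if h_lo < h_dense[0] - 1e-9:
        tang = pts[k] - pts[0]  # robust end direction, not the last segment
        scale = (h_dense[0] - h_lo) / max(tang @ up, 1e-9)
        ext.append([pts[0] - scale * tang])
    body = [pts]
    if h_hi > h_dense[-1] + 1e-9:
        tang = pts[-1] - pts[-1 - k]
        scale = (h_hi - h_dense[-1]) / max(tang @ up, 1e-9)
        body.append([pts[-1] + scale * tang])
    pts = np.vstack([np.asarray(x).reshape(-1, 3) for x in (ext + body)])
    return Curve3D(pts)


def _frame_perp(up: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(up[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(up, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(up, e1)
    return e1, e2


def _histogram_mode(xy: np.ndarray, cell: float) -> np.ndarray:
    """Centroid of the densest cell of a 2D histogram with the given cell size."""
    mins = xy.min(axis=0)
    ij = np.floor((xy - mins) / cell).astype(np.int64)
    keys = ij[:, 0] * 100003 + ij[:, 1]
    uniq, inv, counts = np.unique(keys, return_inverse=True, return_counts=True)
    best = np.argmax(counts)
    return xy[inv == best].mean(axis=0)


def coarse_segment(
    mesh: PlantMesh,
    c_p: Curve3D,
    stem_radius_band: float | None = None,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Partition into region M (id 0) and regions N_i (ids 1..n).

    M is every vertex within a planar radius of c_p (the band defaults to
    ``planar_radius_factor`` times the estimated stem radius); remaining
    vertices are grown into regions over topological neighbours, floating
    components seeding their own region. Returns (region id per vertex,
    estimated stem radius).
    """
    cfg = config or PipelineConfig()
    up = mesh.up_vector
    d = planar_distance(mesh.vertices, c_p, up)
    near = d <= cfg.walk_window
    r_est = float(np.median(d[near])) if near.any() else float(np.median(d))
    band = stem_radius_band if stem_radius_band is not None else cfg.planar_radius_factor * r_est
    is_m = d <= band
    # an organ sweeping through the planar band is spatially near the curve
    # but topologically disconnected from the stem tube: demote minor
    # components of M back to the organ pool
    if is_m.any():
        m_idx = np.where(is_m)[0]
        sub_m = mesh.adjacency[m_idx][:, m_idx]
        _, comp_m = _sp_components(sub_m, directed=False)
        counts = np.bincount(comp_m)
        keep = counts >= 0.25 * counts.max()
        is_m = is_m.copy()
        is_m[m_idx[~keep[comp_m]]] = False
    regions = np.zeros(mesh.n_vertices, dtype=np.int64)
    rest = ~is_m
    if rest.any():
        sub = mesh.adjacency[rest][:, rest]
        _, comp = _sp_components(sub, directed=False)
        regions[rest] = comp + 1
    return regions, r_est


# ----------------------------------------------------------------------
# step 2: tube fit + internodes
# ----------------------------------------------------------------------

def fit_tube(
    points: np.ndarray,
    axis_init: Curve3D,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> TubeFit:
    """Fit the radius of a tube around a fixed axis curve, robustly.

    Alternates a least-squares radius update (mean radial distance of the
    current inliers) with inlier reselection (radial residual within 2.5
    robust standard deviations) until the radius change falls below ``tol``
    mm or ``max_iter`` iterations.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    if len(points) < 10:
        raise ValueError("tube fitting needs at least 10 points")
    d, _ = axis_init.nearest(points)
    if np.ptp(d) < 1e-12 and np.median(d) < 1e-12:
        raise ValueError("degenerate tube fit: all points collinear with the axis")
    r = float(np.median(d))
    mad = float(np.median(np.abs(d - r)))
    sigma = max(1.4826 * mad, 1e-6)
    inliers = np.abs(d - r) <= max(2.5 * sigma, 0.1)
    for _ in range(max_iter):
        if not inliers.any():
            inliers = np.abs(d - r) <= max(np.median(np.abs(d - r)), 0.1)
        r_new = float(d[inliers].mean())
        sigma = max(1.4826 * float(np.median(np.abs(d[inliers] - r_new))), 1e-6)
        new_in = np.abs(d - r_new) <= max(2.5 * sigma, 0.1)
        if abs(r_new - r) < tol and np.array_equal(new_in, inliers):
            r = r_new
            inliers = new_in
            break
        r, inliers = r_new, new_in
    residual = float(np.abs(d[inliers] - r).mean()) if inliers.any() else float("inf")
    return TubeFit(axis=axis_init, radius=r, inliers=inliers, residual=residual)


def segment_stem_internodes(
    mesh: PlantMesh,
    regions: np.ndarray,
    c_p: Curve3D,
    config: PipelineConfig | None = None,
) -> tuple[StemModel, np.ndarray, np.ndarray]:
    """Refine M with a fitted tube; junctions partition the stem.

    Vertices of M inside the tube are stem; bordering vertices (outside the
    tube) cluster by normalised height into junctions and are re-assigned to
    the adjacent region N_i. Returns (stem model, stem internode index per
    vertex (-1 off stem), updated region ids).
    """
    cfg = config or PipelineConfig()
    up = mesh.up_vector
    m_mask = regions == 0
    if not m_mask.any():
        raise StemNotFoundError("coarse region M is empty")
    d_all = planar_distance(mesh.vertices, c_p, up)
    tube = fit_tube(mesh.vertices[m_mask], c_p, max_iter=cfg.tube_max_iter, tol=cfg.tube_tol)
    r = tube.radius
    stem_mask = m_mask & (d_all <= r * cfg.tube_margin)
    border = m_mask & ~stem_mask

    _, t_all = c_p.nearest(mesh.vertices)

    # hand border vertices to the neighbouring organ region
    new_regions = regions.copy()
    new_regions[m_mask] = 0
    adj = mesh.adjacency
    pending = np.where(border)[0]
    for _ in range(10):
        if len(pending) == 0:
            break
        changed = []
        still = []
        for vtx in pending:
            nb = adj.indices[adj.indptr[vtx]: adj.indptr[vtx + 1]]
            nb_regions = new_regions[nb]
            nb_regions = nb_regions[nb_regions > 0]
            if len(nb_regions):
                vals, counts = np.unique(nb_regions, return_counts=True)
                new_regions[vtx] = vals[np.argmax(counts)]
                changed.append(vtx)
            else:
                still.append(vtx)
        if not changed:
            break
        pending = np.asarray(still, dtype=np.int64)
    # leftovers that touch no organ stay stem
    if len(pending):
        stem_mask = stem_mask.copy()
        stem_mask[pending] = True
        new_regions[pending] = 0

    # junctions: organ vertices welded to the stem (the tube border),
    # clustered by 1D connectivity of their normalised heights
    organ = new_regions > 0
    touches_stem = np.zeros(mesh.n_vertices, dtype=bool)
    if organ.any() and stem_mask.any():
        organ_idx = np.where(organ)[0]
        for vtx in organ_idx:
            nb = adj.indices[adj.indptr[vtx]: adj.indptr[vtx + 1]]
            if stem_mask[nb].any():
                touches_stem[vtx] = True
    junctions: list[float] = []
    if touches_stem.any():
        ts = np.sort(t_all[touches_stem])
        splits = np.where(np.diff(ts) > cfg.junction_gap)[0]
        groups = np.split(ts, splits + 1)
        junctions = [float(np.median(g)) for g in groups if len(g) >= 2]
    junctions_arr = np.asarray(sorted(junctions))

    internode = np.full(mesh.n_vertices, -1, dtype=np.int64)
    internode[stem_mask] = np.searchsorted(junctions_arr, t_all[stem_mask])

    hs = mesh.vertices[stem_mask] @ up
    idx_stem = np.where(stem_mask)[0]
    lo, hi = idx_stem[np.argmin(hs)], idx_stem[np.argmax(hs)]
    axis = mesh.vertices[hi] - mesh.vertices[lo]
    axis = axis / np.linalg.norm(axis)
    model = StemModel(
        curve=c_p,
        axis=axis,
        radius=r,
        junction_heights=junctions_arr,
        base_point=mesh.vertices[lo].copy(),
    )
    return model, internode, new_regions


# ----------------------------------------------------------------------
# step 3: petiole separation
# ----------------------------------------------------------------------

def segment_petiole(
    mesh: PlantMesh,
    region_idx: np.ndarray,
    c_p: Curve3D,
    stem_mask: np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, Curve3D | None]:
    """Separate petiole from blade within one coarse region.

    A curve through local centres of mass (binned by on-surface distance from
    the attachment) follows the petiole and extends to the blade apex; a thin
    tube around it, together with the first outside-the-tube vertex B_i,
    delimits the petiole. If the region has no topological connection to the
    stem (floating blade) the step is skipped and everything is blade.
    Returns (petiole vertex ids, leaf vertex ids, petiole curve or None).
    """
    cfg = config or PipelineConfig()
    region_idx = np.asarray(region_idx)
    adj = mesh.adjacency
    attached = False
    for vtx in region_idx:
        nb = adj.indices[adj.indptr[vtx]: adj.indptr[vtx + 1]]
        if stem_mask[nb].any():
            attached = True
            break
    if not attached:
        return np.empty(0, dtype=np.int64), region_idx, None

    pos = mesh.vertices[region_idx]
    d_cp = planar_distance(pos, c_p, mesh.up_vector)
    start_local = int(np.argmin(d_cp))
    sub = mesh.edge_graph()[region_idx][:, region_idx]
    gdist = dijkstra(sub, directed=False, indices=start_local)
    finite = np.isfinite(gdist)
    if not finite.all():
        gdist[~finite] = gdist[finite].max() + 1.0

    nb_bins = max(3, int(np.ceil(gdist.max() / cfg.petiole_bin)))
    bin_of = np.clip((gdist / cfg.petiole_bin).astype(int), 0, nb_bins - 1)
    centroids = []
    for b in range(nb_bins):
        sel = bin_of == b
        if sel.any():
            centroids.append(pos[sel].mean(axis=0))
    if len(centroids) < 2:
        return np.empty(0, dtype=np.int64), region_idx, None
    curve = Curve3D(np.asarray(centroids))

    d_curve, _ = curve.nearest(pos)
    neck_bins = (bin_of >= 1) & (bin_of <= 3)
    r_pet = float(np.median(d_curve[neck_bins])) if neck_bins.any() else float(np.median(d_curve))
    r_tube = max(cfg.petiole_tube_factor * r_pet, r_pet + 1.0)
    inside = d_curve <= r_tube
    outside = ~inside
    if not outside.any():
        # no blade beyond the tube: the whole region is a (bladeless) petiole
        return region_idx, np.empty(0, dtype=np.int64), curve
    b_dist = gdist[outside].min()
    pet_local = inside & (gdist < b_dist)
    if not pet_local.any():
        warnings.warn("region has no tubular neck; petiole empty (sessile blade)")
    return region_idx[pet_local], region_idx[~pet_local], curve


# ----------------------------------------------------------------------
# step 4: leaf stage
# ----------------------------------------------------------------------

def farthest_pair(points: np.ndarray) -> tuple[int, int]:
    """Indices of the two farthest-apart points (convex-hull accelerated)."""
    pts = np.asarray(points, float)
    cand = np.arange(len(pts))
    if len(pts) > 50:
        try:
            cand = ConvexHull(pts).vertices
        except QhullError:
            pass
    sub = pts[cand]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return int(cand[i]), int(cand[j])


def detect_and_split_merged_leaf(
    mesh: PlantMesh,
    leaf_idx: np.ndarray,
    median_leaf_area: float,
    config: PipelineConfig | None = None,
) -> list[np.ndarray]:
    """Split a region holding two fused leaves.

    If the region's surface area is far above the median leaf (factor
    ``merged_leaf_tau``), the two farthest-apart vertices f1, f2 are found
    and the region is cut by the plane through their centroid with normal
    along centroid->f2. Otherwise the region is returned unchanged.
    """
    cfg = config or PipelineConfig()
    leaf_idx = np.asarray(leaf_idx)
    area = region_surface_area(mesh, leaf_idx)
    if median_leaf_area <= 0 or area <= cfg.merged_leaf_tau * median_leaf_area:
        return [leaf_idx]
    if len(leaf_idx) < cfg.min_split_size:
        warnings.warn("region too small to split; returned unchanged")
        return [leaf_idx]
    pts = mesh.vertices[leaf_idx]
    i, j = farthest_pair(pts)
    fc = 0.5 * (pts[i] + pts[j])
    normal = pts[j] - fc
    normal = normal / np.linalg.norm(normal)
    side = (pts - fc) @ normal > 0
    if side.all() or not side.any():
        return [leaf_idx]
    return [leaf_idx[~side], leaf_idx[side]]


def region_surface_area(mesh: PlantMesh, idx: np.ndarray) -> float:
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[idx] = True
    inside = mask[mesh.triangles].sum(axis=1) >= 2
    if not inside.any():
        return 0.0
    _, areas = mesh.triangle_normals_areas()
    return float(areas[inside].sum())


def segment_leaf_sagittal(
    mesh: PlantMesh,
    leaf_idx: np.ndarray,
    c_p: Curve3D,
    stem_axis: np.ndarray,
) -> np.ndarray:
    """LEFT/RIGHT per leaf vertex by the sign of the planar angle.

    Vertices are projected onto the plane with the main stem axis as normal;
    the side is the sign of the signed angle between (stem->apex) and
    (stem->vertex), ties broken to LEFT.
    """
    leaf_idx = np.asarray(leaf_idx)
    pts = mesh.vertices[leaf_idx]
    centroid = pts.mean(axis=0)
    _, t = c_p.nearest(centroid[None, :])
    ref = c_p.evaluate(t)[0]
    a = np.asarray(stem_axis, float)
    a = a / np.linalg.norm(a)
    e1, e2 = _frame_perp(a)
    p2 = np.column_stack([(pts - ref) @ e1, (pts - ref) @ e2])
    r2 = np.linalg.norm(p2, axis=1)
    apex_local = int(np.argmax(r2))
    av = p2[apex_local]
    if np.linalg.norm(av) < 1e-9:
        raise ValueError("leaf apex coincides with the stem reference point")
    cross = av[0] * p2[:, 1] - av[1] * p2[:, 0]
    side = np.where(cross > 1e-6 * max(np.linalg.norm(av), 1.0), mc.SIDE_RIGHT, mc.SIDE_LEFT)
    return side.astype(np.int64)


def segment_leaf_transversal(
    mesh: PlantMesh,
    leaf_idx: np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, bool]:
    """ADAXIAL/ABAXIAL per leaf vertex by iterative normal clustering.

    Start from the mean leaf normal; sort vertices by whether their normal
    is within pi/2 of it; recompute the mean over one cluster; repeat until
    the assignment no longer changes. Returns (surface labels, two_sided):
    ``two_sided`` is False for an open single sheet (one cluster empty).
    """
    cfg = config or PipelineConfig()
    leaf_idx = np.asarray(leaf_idx)
    normals = mesh.vertex_normals[leaf_idx]
    defined = mesh.normal_defined[leaf_idx]
    surface = np.full(len(leaf_idx), mc.SURFACE_ADAXIAL, dtype=np.int64)
    if defined.sum() == 0:
        return surface, False
    nd = normals[defined]
    vn = nd.mean(axis=0)
    if np.linalg.norm(vn) < 1e-12:
        vn = nd[0]
    vn = vn / np.linalg.norm(vn)
    assign = nd @ vn > 0.0
    for _ in range(cfg.transversal_max_iter):
        if assign.any():
            vn_new = nd[assign].mean(axis=0)
        else:
            vn_new = -vn
        nrm = np.linalg.norm(vn_new)
        if nrm < 1e-12:
            break
        vn = vn_new / nrm
        new_assign = nd @ vn > 0.0
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    two_sided = bool(assign.any() and (~assign).any())
    # name the up-facing cluster adaxial
    up = mesh.up_vector
    cluster_mean = nd[assign].mean(axis=0) if assign.any() else vn
    ad_value = assign if cluster_mean @ up >= 0 else ~assign
    surf_def = np.where(ad_value, mc.SURFACE_ADAXIAL, mc.SURFACE_ABAXIAL)
    surface[defined] = surf_def
    if (~defined).any():
        # undefined normals inherit the majority label of their neighbours
        tree = cKDTree(mesh.vertices[leaf_idx[defined]])
        _, nearest = tree.query(mesh.vertices[leaf_idx[~defined]])
        surface[~defined] = surf_def[nearest]
    return surface, two_sided


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------

def segment_plant(
    mesh: PlantMesh, config: PipelineConfig | None = None
) -> SegmentationResult:
    """Run the four segmentation stages in order; every vertex ends labelled."""
    cfg = config or PipelineConfig()
    c_p = fit_stem_curve(mesh, cfg)
    regions, _ = coarse_segment(mesh, c_p, config=cfg)
    n_coarse = int(regions.max())
    stem_model, internode, regions = segment_stem_internodes(mesh, regions, c_p, cfg)
    stem_mask = regions == 0

    labels = SegmentationLabels.empty(mesh.n_vertices)
    labels.organ[stem_mask] = mc.STEM
    labels.index[stem_mask] = internode[stem_mask]

    # pass 1: petiole/blade separation per region
    region_ids = [rid for rid in np.unique(regions) if rid > 0]
    entries = []  # (sort_height, petiole idx, leaf idx, curve)
    debris = []
    up = mesh.up_vector
    for rid in region_ids:
        idx = np.where(regions == rid)[0]
        if len(idx) < cfg.min_region_size:
            debris.append(idx)
            continue
        pet_idx, leaf_idx, curve = segment_petiole(mesh, idx, c_p, stem_mask, cfg)
        if len(pet_idx) and len(leaf_idx) == 0:
            # bladeless stub: treat as petiole with no leaf
            entries.append((_attach_height(mesh, pet_idx, c_p), pet_idx, leaf_idx, curve))
            continue
        entries.append((_attach_height(mesh, leaf_idx if not len(pet_idx) else pet_idx, c_p),
                        pet_idx, leaf_idx, curve))

    # pass 2: merged-leaf detection needs the median leaf size
    leaf_areas = [region_surface_area(mesh, e[2]) for e in entries if len(e[2])]
    median_area = float(np.median(leaf_areas)) if leaf_areas else 0.0

    entries.sort(key=lambda e: e[0])
    leaf_counter = 0
    final_leaves: list[np.ndarray] = []
    for _, pet_idx, leaf_idx, curve in entries:
        if len(leaf_idx) == 0:
            if len(pet_idx):
                labels.organ[pet_idx] = mc.PETIOLE
                labels.index[pet_idx] = leaf_counter
                leaf_counter += 1
            continue
        pieces = detect_and_split_merged_leaf(mesh, leaf_idx, median_area, cfg)
        if len(pieces) == 2 and len(pet_idx):
            # the petiole belongs to the half nearer its far end
            tip = mesh.vertices[pet_idx].mean(axis=0)
            d0 = np.min(np.linalg.norm(mesh.vertices[pieces[0]] - tip, axis=1))
            d1 = np.min(np.linalg.norm(mesh.vertices[pieces[1]] - tip, axis=1))
            if d1 < d0:
                pieces = [pieces[1], pieces[0]]
        for k, piece in enumerate(pieces):
            li = leaf_counter
            leaf_counter += 1
            labels.organ[piece] = mc.LEAF
            labels.index[piece] = li
            final_leaves.append(piece)
            if k == 0 and len(pet_idx):
                labels.organ[pet_idx] = mc.PETIOLE
                labels.index[pet_idx] = li

    # leaf sub-labels
    for piece in final_leaves:
        try:
            labels.side[piece] = segment_leaf_sagittal(mesh, piece, c_p, stem_model.axis)
        except ValueError:
            labels.side[piece] = mc.SIDE_LEFT
        surf, _ = segment_leaf_transversal(mesh, piece, cfg)
        labels.surface[piece] = surf

    # debris: fold small fragments into the nearest labelled organ
    if debris:
        labelled = labels.organ != mc.UNASSIGNED
        if labelled.any():
            tree = cKDTree(mesh.vertices[labelled])
            src = np.where(labelled)[0]
            for idx in debris:
                _, nearest = tree.query(mesh.vertices[idx])
                donor = src[nearest]
                labels.organ[idx] = labels.organ[donor]
                labels.index[idx] = labels.index[donor]
                labels.side[idx] = labels.side[donor]
                labels.surface[idx] = labels.surface[donor]

    # absolute completeness: anything still unassigned joins the stem
    left = labels.organ == mc.UNASSIGNED
    if left.any():
        labels.organ[left] = mc.STEM
        labels.index[left] = 0

    return SegmentationResult(
        labels=labels,
        stem_model=stem_model,
        n_coarse_regions=n_coarse,
        diagnostics={"n_leaves": leaf_counter, "n_junctions": len(stem_model.junction_heights)},
    )


def _attach_height(mesh: PlantMesh, idx: np.ndarray, c_p: Curve3D) -> float:
    if len(idx) == 0:
        return float("inf")
    pts = mesh.vertices[idx]
    d = planar_distance(pts, c_p, mesh.up_vector)
    anchor = pts[np.argmin(d)]
    _, t = c_p.nearest(anchor[None, :])
    return float(t[0])
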