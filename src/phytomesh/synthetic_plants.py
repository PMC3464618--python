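"""Procedural cotton-like plant meshes with exact ground truth.

Stands in for photogrammetric reconstructions: a tubular main stem, petioles
attached at distinct heights, and lobed bilaterally symmetric leaf blades
with finite thickness. Every vertex carries a true organ label, and the true
phenotypic parameters (developed leaf width/length, blade area, petiole
length, angles) are recorded exactly, so segmentation and measurement can be
scored against a gold standard. Reconstruction defects seen in multi-view
meshes — holes, detached petioles leaving a floating blade, two leaves fused
together — can be injected on top.

Blade geometry: the developed (laid-flat) blade is a three-lobed, bilaterally
symmetric outline of maximal width W and length L. It is mapped isometrically
onto a circular arc bent about the coronal axis, so the developed length
always equals the arc length and the developed dimensions are invariant to
``blade_bend`` — exactly the destructive laid-flat measurement convention.
The blade has two offset sheets (adaxial/abaxial) separated by the leaf
thickness, closed by a thin side wall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from phytomesh import mesh_core as mc
from phytomesh.mesh_core import PlantMesh, SegmentationLabels


@dataclass
class LeafSpec:
    """Parameters of one petiole + blade unit (all lengths in mm, angles deg)."""

    attachment_height: float
    azimuth: float
    petiole_length: float
    petiole_initiation_angle: float
    leaf_width: float
    leaf_length: float
    leaf_thickness: float = 1.0
    leaf_inclination: float = 70.0
    blade_bend: float = 0.0  # total bend angle (radians) about the coronal axis
    petiole_radius: float = 1.2


@dataclass
class PlantSpec:
    """Full parameter set of a synthetic plant."""

    stem_height: float = 170.9
    stem_radius: float = 3.0
    stem_inclination: float = 0.0  # deg from the up vector
    stem_azimuth: float = 0.0  # deg, direction the stem leans toward
    leaves: list[LeafSpec] = field(default_factory=list)
    mesh_resolution: int = 6000  # target triangle count
    base_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_offset = np.asarray(self.base_offset, dtype=float)
        if self.stem_height <= 0 or self.stem_radius <= 0:
            raise ValueError("stem dimensions must be positive")
        if not self.leaves:
            raise ValueError("a plant needs at least one leaf")
        heights = [lf.attachment_height for lf in self.leaves]
        if not all(b > a for a, b in zip(heights, heights[1:])):
            raise ValueError("attachment heights must be strictly increasing")
        for lf in self.leaves:
            if min(lf.petiole_length, lf.leaf_width, lf.leaf_length, lf.leaf_thickness) <= 0:
                raise ValueError("all leaf dimensions must be positive")
            if not (0.0 <= lf.azimuth < 360.0):
                raise ValueError("azimuth must be in [0, 360)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


@dataclass
class DefectOptions:
    """Reconstruction-defect injection parameters."""

    hole_fraction: float = 0.0
    detach_petiole: tuple[int, ...] = ()
    merge_leaves: tuple[int, int] | None = None
    vertex_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hole_fraction <= 1.0):
            raise ValueError("hole_fraction must be in [0, 1]")
        if self.merge_leaves is not None and self.merge_leaves[0] == self.merge_leaves[1]:
            raise ValueError("merged leaves must be distinct")


@dataclass
class GroundTruth:
    """True labels and parameters realised on the emitted mesh."""

    labels: SegmentationLabels
    leaf_ids: np.ndarray  # persistent identity per leaf index (tracking gold standard)
    stem_height: float  # vertical extent of the stem part, mm
    stem_length: float  # stem axis arc length, mm
    stem_inclination: float  # deg
    stem_base: np.ndarray
    stem_axis: np.ndarray
    junction_heights: np.ndarray  # normalised petiole attachment heights in [0, 1]
    leaf_params: pd.DataFrame  # one row per leaf index
    merged_pairs: list = field(default_factory=list)
    detached: list = field(default_factory=list)

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            self.labels.copy(), self.leaf_ids.copy(), self.stem_height, self.stem_length,
            self.stem_inclination, self.stem_base.copy(), self.stem_axis.copy(),
            self.junction_heights.copy(), self.leaf_params.copy(),
            list(self.merged_pairs), list(self.detached),
        )


@dataclass
class GrowthParams:
    """Per-step changes applied by :func:`grow_sequence`."""

    stem_scale: float = 1.10
    leaf_scale: float = 1.12
    azimuth_drift: float = 10.0  # deg bound on per-leaf azimuth change per step
    new_leaves_per_step: int = 1
    repot_rotation: float = 360.0  # deg bound on whole-plant rotation per step
    repot_translation_sd: float = 5.0  # mm, horizontal


# ----------------------------------------------------------------------
# default study conditions
# ----------------------------------------------------------------------

def default_spec(seed: int = 0, n_leaves: int | None = None) -> PlantSpec:
    """A realistic vegetative-stage cotton-like plant.

    Dimensions are sampled around field-observed means (stem height
    ~170.9 mm, leaf width ~88.9 mm, leaf length ~78.9 mm); leaf count
    defaults to 5-8, azimuths follow a jittered spiral phyllotaxis.
    """
    rng = np.random.default_rng(seed)
    if n_leaves is None:
        n_leaves = int(rng.integers(5, 9))
    stem_height = float(np.clip(rng.normal(170.9, 12.0), 140.0, 205.0))
    heights = np.sort(rng.uniform(0.22, 0.90, n_leaves)) * stem_height
    # enforce a minimal internode length so junctions stay resolvable
    for k in range(1, n_leaves):
        heights[k] = max(heights[k], heights[k - 1] + 9.0)
    heights = np.minimum(heights, 0.94 * stem_height)
    for k in range(n_leaves - 2, -1, -1):
        heights[k] = min(heights[k], heights[k + 1] - 9.0)
    leaves = []
    for k in range(n_leaves):
        leaves.append(
            LeafSpec(
                attachment_height=float(heights[k]),
                azimuth=float((137.5 * k + rng.normal(0.0, 12.0)) % 360.0),
                petiole_length=float(np.clip(rng.normal(45.0, 8.0), 28.0, 70.0)),
                petiole_initiation_angle=float(rng.uniform(40.0, 75.0)),
                leaf_width=float(np.clip(rng.normal(88.9, 10.0), 55.0, 120.0)),
                leaf_length=float(np.clip(rng.normal(78.9, 9.0), 50.0, 110.0)),
                leaf_thickness=1.0,
                leaf_inclination=float(rng.uniform(55.0, 85.0)),
                blade_bend=float(rng.uniform(0.0, 0.7)),
            )
        )
    return PlantSpec(
        stem_height=stem_height,
        stem_radius=3.0,
        stem_inclination=float(rng.uniform(0.0, 6.0)),
        stem_azimuth=float(rng.uniform(0.0, 360.0)),
        leaves=leaves,
        seed=seed,
    )


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------

def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def _make_tube(p0, p1, radius, n_theta, n_axial, cap_start=True, cap_end=True):
    """Capped straight tube. Returns (vertices, triangles, end_ring, end_center)."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    axis = p1 - p0
    e1, e2 = _orthonormal_frame(axis)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    ring = radius * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
    stations = np.linspace(0.0, 1.0, n_axial + 1)
    verts = (p0 + stations[:, None] * axis)[:, None, :] + ring[None, :, :]
    verts = verts.reshape(-1, 3)
    tris = []
    for i in range(n_axial):
        base0, base1 = i * n_theta, (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            a, b, c, d = base0 + j, base0 + jn, base1 + j, base1 + jn
            tris.append((a, c, b))
            tris.append((b, c, d))
    extra = []
    if cap_start:
        ci = len(verts) + len(extra)
        extra.append(p0)
        for j in range(n_theta):
            tris.append((ci, j, (j + 1) % n_theta))
    end_center = None
    if cap_end:
        ci = len(verts) + len(extra)
        extra.append(p1)
        end_center = ci
        base = n_axial * n_theta
        for j in range(n_theta):
            tris.append((ci, base + (j + 1) % n_theta, base + j))
    if extra:
        verts = np.vstack([verts, np.asarray(extra)])
    end_ring = np.arange(n_axial * n_theta, (n_axial + 1) * n_theta)
    return verts, np.asarray(tris, dtype=np.int64), end_ring, end_center


_BASE_TRUNCATION = 0.12  # blades flare immediately at the petiole insertion


def _lobed_half_width(u: np.ndarray) -> np.ndarray:
    """Smooth 3-lobed half-width profile on [0, 1], normalised to max 1.

    The profile is truncated at the base (u=0 has ~40% of the maximal
    half-width) the way cotton blades flare straight out of the petiole;
    the apex (u=1) closes to a point.
    """
    def raw(t):
        return np.sin(np.pi * t) ** 0.8 * (1.0 + 0.16 * np.cos(3.0 * np.pi * (t - 0.5)))

    u = np.asarray(u, float)
    t = _BASE_TRUNCATION + (1.0 - _BASE_TRUNCATION) * u
    dense = _BASE_TRUNCATION + (1.0 - _BASE_TRUNCATION) * np.linspace(0.0, 1.0, 2001)
    return raw(t) / np.max(raw(dense))


def _half_width_argmax() -> float:
    dense = np.linspace(0.0, 1.0, 2001)
    return float(dense[np.argmax(_lobed_half_width(dense))])


def lobed_outline(width: float, length: float, n: int = 400) -> np.ndarray:
    """Developed (laid-flat) blade outline polygon, (2n, 2) array in mm.

    The polygon runs along the +y edge, through the apex, back along the -y
    edge, and closes across the truncated base."""
    u = np.linspace(0.0, 1.0, n)
    h = 0.5 * width * _lobed_half_width(u)
    s = u * length
    top = np.column_stack([s, h])
    bottom = np.column_stack([s[::-1], -h[::-1]])
    return np.vstack([top, bottom])


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _build_blade(base_point, midrib_dir, lateral_dir, normal_dir, lf: LeafSpec,
                 nu: int, nv: int):
    """Two-sheet lobed blade bent about the coronal axis.

    Returns (vertices, triangles, gt) where gt carries the realised developed
    dimensions, area, and per-vertex surface/side codes. The map from
    developed coordinates (s, y) to the mid-surface is an isometry, so the
    developed width/length/area are exact whatever the bend.
    """
    L, W, t = lf.leaf_length, lf.leaf_width, lf.leaf_thickness
    beta = lf.blade_bend
    m, l, nrm = (np.asarray(v, float) for v in (midrib_dir, lateral_dir, normal_dir))
    s0 = 3.0  # short basal stub between the petiole tip and the blade base row

    u_grid = np.unique(np.concatenate([np.linspace(0.0, 1.0, nu + 1), [_half_width_argmax()]]))
    u_rows = u_grid[:-1]  # base row included; the apex closes to a point
    h = 0.5 * W * _lobed_half_width(u_rows)
    v_param = np.linspace(-1.0, 1.0, nv)

    # midrib arc and local frames: station 0 = basal stub, then rows, then apex
    s = np.concatenate([[0.0], s0 + u_rows * L, [s0 + L]])
    if abs(beta) > 1e-9:
        R = L / beta
        phi = s / R
        c = base_point + R * np.sin(phi)[:, None] * m - R * (1 - np.cos(phi))[:, None] * nrm
        tang = np.cos(phi)[:, None] * m - np.sin(phi)[:, None] * nrm
        nloc = np.sin(phi)[:, None] * m + np.cos(phi)[:, None] * nrm
    else:
        c = base_point + s[:, None] * m
        tang = np.tile(m, (len(s), 1))
        nloc = np.tile(nrm, (len(s), 1))

    def sheet(offset_sign: int):
        verts = [c[0] + offset_sign * 0.5 * t * nloc[0]]  # base point
        for i, ui in enumerate(u_rows):
            row = c[i + 1] + (v_param * h[i])[:, None] * l + offset_sign * 0.5 * t * nloc[i + 1]
            verts.extend(row)
        verts.append(c[-1] + offset_sign * 0.5 * t * nloc[-1])  # apex
        verts = np.asarray(verts)
        n_rows = len(u_rows)
        apex = 1 + n_rows * nv

        def rid(i, j):
            return 1 + i * nv + j

        tris = []
        for j in range(nv - 1):
            tris.append((0, rid(0, j), rid(0, j + 1)))
        for i in range(n_rows - 1):
            for j in range(nv - 1):
                a, b = rid(i, j), rid(i, j + 1)
                cc, d = rid(i + 1, j), rid(i + 1, j + 1)
                tris.append((a, cc, b))
                tris.append((b, cc, d))
        for j in range(nv - 1):
            tris.append((apex, rid(n_rows - 1, j + 1), rid(n_rows - 1, j)))
        tris = np.asarray(tris, dtype=np.int64)
        # orient triangle winding toward the sheet's outward direction
        tn = np.cross(verts[tris[:, 1]] - verts[tris[:, 0]], verts[tris[:, 2]] - verts[tris[:, 0]])
        row_of = np.clip(((tris.min(axis=1) - 1) // nv), 0, n_rows - 1)
        want = offset_sign * nloc[row_of + 1]
        flip = np.einsum("ij,ij->i", tn, want) < 0
        tris[flip] = tris[flip][:, [0, 2, 1]]
        # boundary loop: base, left edge up, apex, right edge down
        loop = [0] + [rid(i, 0) for i in range(n_rows)] + [apex] + \
               [rid(i, nv - 1) for i in range(n_rows - 1, -1, -1)]
        side = np.zeros(len(verts), dtype=np.int64)
        for i in range(n_rows):
            for j in range(nv):
                # the midrib (v = 0) counts as LEFT, matching the sagittal
                # segmentation's tie-break convention
                side[rid(i, j)] = mc.SIDE_LEFT if v_param[j] <= 0 else mc.SIDE_RIGHT
        return verts, tris, np.asarray(loop), side, apex

    v_ad, t_ad, loop_ad, side_ad, _ = sheet(+1)
    v_ab, t_ab, loop_ab, side_ab, _ = sheet(-1)
    n_ad = len(v_ad)
    verts = np.vstack([v_ad, v_ab])
    tris = [t_ad, t_ab + n_ad]
    wall = []
    for k in range(len(loop_ad)):
        p, q = loop_ad[k], loop_ad[(k + 1) % len(loop_ad)]
        pb, qb = loop_ab[k] + n_ad, loop_ab[(k + 1) % len(loop_ab)] + n_ad
        wall.append((p, q, pb))
        wall.append((q, qb, pb))
    tris.append(np.asarray(wall, dtype=np.int64))
    tris = np.vstack(tris)

    surface = np.concatenate([
        np.full(n_ad, mc.SURFACE_ADAXIAL, np.int64),
        np.full(len(v_ab), mc.SURFACE_ABAXIAL, np.int64),
    ])
    side = np.concatenate([side_ad, side_ab])
    outline_s = np.concatenate([u_rows * L, [L]])
    outline_h = np.concatenate([h, [0.0]])
    poly = np.vstack([
        np.column_stack([outline_s, outline_h]),
        np.column_stack([outline_s[::-1], -outline_h[::-1]]),
    ])
    chord = c[-1] - c[0]
    gt = {
        "width": float(2.0 * h.max()),
        "length": float(L),
        "area": float(_polygon_area(poly)),
        "thickness": float(t),
        "chord": chord,
        "base_index": 0,
        "apex_index_local": 1 + len(u_rows) * nv,
    }
    return verts, tris, surface, side, gt


# ----------------------------------------------------------------------
# main generator
# ----------------------------------------------------------------------

def generate_plant(spec: PlantSpec) -> tuple[PlantMesh, GroundTruth]:
    """Realise a spec as a labelled triangle mesh. Deterministic per spec."""
    up = np.array([0.0, 0.0, 1.0])
    rho = float(np.clip(np.sqrt(spec.mesh_resolution / 6000.0), 0.5, 2.5))
    n_theta_stem = max(8, round(10 * rho))
    n_ax_stem = max(24, round(40 * rho))
    n_theta_pet = max(4, round(6 * rho))
    nu_blade = max(8, round(16 * rho))
    nv_blade = max(5, int(2 * round((9 * rho) / 2) + 1))  # odd
    if n_theta_pet < 4:
        raise ValueError(
            f"mesh_resolution {spec.mesh_resolution} too low to represent a petiole of "
            f"radius {min(l.petiole_radius for l in spec.leaves):.2f} mm"
        )

    # stem axis
    inc = np.deg2rad(spec.stem_inclination)
    az = np.deg2rad(spec.stem_azimuth)
    lean = np.array([np.cos(az), np.sin(az), 0.0])
    axis = np.cos(inc) * up + np.sin(inc) * lean
    base = spec.base_offset.astype(float)
    top = base + spec.stem_height * axis

    verts_parts: list[np.ndarray] = []
    tris_parts: list[np.ndarray] = []
    organ_parts: list[np.ndarray] = []
    index_parts: list[np.ndarray] = []
    side_parts: list[np.ndarray] = []
    surf_parts: list[np.ndarray] = []
    offset = 0

    def add_part(v, t, organ, index, side=None, surface=None):
        nonlocal offset
        verts_parts.append(v)
        tris_parts.append(t + offset)
        n = len(v)
        organ_parts.append(np.full(n, organ, np.int64))
        index_parts.append(index if isinstance(index, np.ndarray) else np.full(n, index, np.int64))
        side_parts.append(side if side is not None else np.full(n, mc.SIDE_UNDEFINED, np.int64))
        surf_parts.append(surface if surface is not None else np.full(n, mc.SURFACE_UNDEFINED, np.int64))
        start = offset
        offset += n
        return start

    # --- stem ---
    sv, st, _, _ = _make_tube(base, top, spec.stem_radius, n_theta_stem, n_ax_stem)
    s_along = (sv - base) @ axis
    junctions = np.asarray([lf.attachment_height for lf in spec.leaves])
    internode = np.searchsorted(junctions, s_along)
    add_part(sv, st, mc.STEM, internode.astype(np.int64))
    stem_vertex_count = len(sv)
    stem_tree = cKDTree(sv)

    leaf_rows = []
    extra_tris = []

    for li, lf in enumerate(spec.leaves):
        phi = np.deg2rad(lf.azimuth)
        e1, e2 = _orthonormal_frame(axis)
        radial = np.cos(phi) * e1 + np.sin(phi) * e2
        alpha = np.deg2rad(lf.petiole_initiation_angle)
        pdir = np.cos(alpha) * axis + np.sin(alpha) * radial
        p0 = base + lf.attachment_height * axis
        core = spec.stem_radius / max(np.sin(alpha), 0.3)
        # the petiole runs from the stem surface to the blade base row; the
        # short basal stub inside the blade builder is part of that length
        tube_len = max(lf.petiole_length - 3.0, 5.0)
        p1 = p0 + (core + tube_len) * pdir

        n_ax_pet = max(5, round((core + lf.petiole_length) / 4.0))
        pv, pt, pet_ring, pet_tip = _make_tube(
            p0, p1, lf.petiole_radius, n_theta_pet, n_ax_pet
        )
        pet_start = add_part(pv, pt, mc.PETIOLE, li)

        # stitch petiole base ring into the stem surface (topological weld)
        ring_global = pet_start + np.arange(n_theta_pet)
        _, nearest = stem_tree.query(pv[:n_theta_pet])
        for j in range(n_theta_pet):
            jn = (j + 1) % n_theta_pet
            extra_tris.append((ring_global[j], ring_global[jn], int(nearest[j])))

        # blade frame: midrib leaves the petiole tip at the leaf inclination
        iota = np.deg2rad(lf.leaf_inclination)
        m = np.cos(iota) * axis + np.sin(iota) * radial
        m /= np.linalg.norm(m)
        lat = np.cross(axis, m)
        lat /= np.linalg.norm(lat)
        nrm = np.cross(m, lat)
        if np.dot(nrm, axis) < 0:
            nrm = -nrm
            lat = -lat
        bv, bt, surf, side, bgt = _build_blade(p1, m, lat, nrm, lf, nu_blade, nv_blade)
        blade_start = add_part(bv, bt, mc.LEAF, li, side=side, surface=surf)

        # stitch blade base points (local index 0 in each sheet) to the petiole tip
        n_ad = len(bv) // 2
        ad_base = blade_start + bgt["base_index"]
        ab_base = blade_start + n_ad
        tip = pet_start + pet_tip
        ring0 = pet_start + pet_ring[0]
        extra_tris.append((ad_base, ab_base, tip))
        extra_tris.append((ad_base, tip, ring0))
        extra_tris.append((ab_base, ring0, tip))

        chord = bgt["chord"]
        chord_sag = chord - np.dot(chord, lat) * lat  # already in the sagittal plane
        incl_true = np.degrees(
            np.arccos(np.clip(np.dot(chord_sag / np.linalg.norm(chord_sag), axis), -1, 1))
        )
        leaf_rows.append(
            dict(
                leaf=li,
                attachment_height=lf.attachment_height,
                azimuth=lf.azimuth,
                petiole_length=lf.petiole_length,
                initiation_angle=lf.petiole_initiation_angle,
                width=bgt["width"],
                length=bgt["length"],
                area=bgt["area"],
                thickness=bgt["thickness"],
                inclination=incl_true,
                apex_vertex=blade_start + bgt["apex_index_local"],
            )
        )

    vertices = np.vstack(verts_parts)
    triangles = np.vstack(tris_parts + [np.asarray(extra_tris, dtype=np.int64)])
    mesh = PlantMesh(vertices, triangles, up_vector=up)
    labels = SegmentationLabels(
        organ=np.concatenate(organ_parts),
        index=np.concatenate(index_parts),
        side=np.concatenate(side_parts),
        surface=np.concatenate(surf_parts),
    )
    stem_heights = vertices[:stem_vertex_count] @ up
    gt = GroundTruth(
        labels=labels,
        leaf_ids=np.arange(spec.n_leaves, dtype=np.int64),
        stem_height=float(stem_heights.max() - stem_heights.min()),
        stem_length=float(spec.stem_height),
        stem_inclination=float(spec.stem_inclination),
        stem_base=base.copy(),
        stem_axis=axis.copy(),
        junction_heights=junctions / spec.stem_height,
        leaf_params=pd.DataFrame(leaf_rows).set_index("leaf"),
    )
    return mesh, gt


# ----------------------------------------------------------------------
# growth sequences
# ----------------------------------------------------------------------

def grow_sequence(
    spec: PlantSpec,
    n_timepoints: int,
    growth: GrowthParams | None = None,
    seed: int | None = None,
    match_gate: float = 45.0,
) -> list[tuple[PlantMesh, GroundTruth]]:
    """Grow a plant over consecutive imaging dates.

    Organ identities are carried in ``GroundTruth.leaf_ids`` — the tracking
    gold standard. New leaves appear near the apex; attachment order is
    preserved; each step applies a whole-plant re-potting rotation and
    translation plus a bounded per-leaf azimuth drift.
    """
    if n_timepoints < 2:
        raise ValueError("need at least two time-points")
    growth = growth or GrowthParams()
    if growth.azimuth_drift > match_gate:
        warnings.warn(
            "azimuth drift bound exceeds the matcher's angular gate; "
            "leaf correspondence becomes unidentifiable by construction"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    out = []
    cur = spec
    ids = np.arange(spec.n_leaves, dtype=np.int64)
    next_id = spec.n_leaves
    mean_w = float(np.mean([lf.leaf_width for lf in spec.leaves]))
    mean_l = float(np.mean([lf.leaf_length for lf in spec.leaves]))

    for t in range(n_timepoints):
        mesh, gt = generate_plant(cur)
        gt.leaf_ids = ids.copy()
        out.append((mesh, gt))
        if t == n_timepoints - 1:
            break
        # advance the spec one step
        new_h = cur.stem_height * growth.stem_scale
        scale_h = growth.stem_scale
        leaves = []
        for lf in cur.leaves:
            drift = rng.uniform(-growth.azimuth_drift, growth.azimuth_drift)
            leaves.append(
                replace(
                    lf,
                    attachment_height=lf.attachment_height * scale_h,
                    azimuth=float((lf.azimuth + drift) % 360.0),
                    petiole_length=lf.petiole_length * growth.leaf_scale ** 0.5,
                    leaf_width=lf.leaf_width * growth.leaf_scale ** 0.5,
                    leaf_length=lf.leaf_length * growth.leaf_scale ** 0.5,
                )
            )
        new_ids = list(ids)
        for _ in range(growth.new_leaves_per_step):
            last = leaves[-1].attachment_height
            att = min(0.5 * (last + 0.95 * new_h), 0.95 * new_h)
            if att <= last + 4.0:
                att = min(last + 4.0, 0.97 * new_h)
            leaves.append(
                LeafSpec(
                    attachment_height=float(att),
                    azimuth=float(rng.uniform(0.0, 360.0)),
                    petiole_length=float(rng.uniform(22.0, 32.0)),
                    petiole_initiation_angle=float(rng.uniform(35.0, 60.0)),
                    leaf_width=0.55 * mean_w,
                    leaf_length=0.55 * mean_l,
                    leaf_thickness=leaves[-1].leaf_thickness,
                    leaf_inclination=float(rng.uniform(45.0, 70.0)),
                    blade_bend=float(rng.uniform(0.0, 0.4)),
                )
            )
            new_ids.append(next_id)
            next_id += 1
        ids = np.asarray(new_ids, dtype=np.int64)
        rot = rng.uniform(0.0, growth.repot_rotation)
        shift = np.concatenate([rng.normal(0.0, growth.repot_translation_sd, 2), [0.0]]) \
            if growth.repot_translation_sd > 0 else np.zeros(3)
        cur = replace(
            cur,
            stem_height=new_h,
            stem_azimuth=float((cur.stem_azimuth + rot) % 360.0),
            leaves=[replace(lf, azimuth=float((lf.azimuth + rot) % 360.0)) for lf in leaves],
            base_offset=cur.base_offset + shift,
        )
    return out


# ----------------------------------------------------------------------
# defects
# ----------------------------------------------------------------------

def perturb_mesh(
    mesh: PlantMesh, gt: GroundTruth, opts: DefectOptions, seed: int = 0
) -> tuple[PlantMesh, GroundTruth]:
    """Inject reconstruction defects; ground truth is updated consistently
    (vertices removed by a defect are dropped from the labels)."""
    rng = np.random.default_rng(seed)
    gt = gt.copy()
    vertices = mesh.vertices.copy()
    triangles = mesh.triangles.copy()
    labels = gt.labels

    for li in opts.detach_petiole:
        if li not in set(labels.petiole_indices) and li not in set(labels.leaf_indices):
            raise ValueError(f"cannot detach petiole of nonexistent leaf {li}")

    if opts.merge_leaves is not None:
        i, j = opts.merge_leaves
        vi = np.where(labels.leaf_mask(i))[0]
        vj = np.where(labels.leaf_mask(j))[0]
        if len(vi) == 0 or len(vj) == 0:
            raise ValueError(f"cannot merge nonexistent leaves {opts.merge_leaves}")
        tree = cKDTree(vertices[vj])
        d, nearest = tree.query(vertices[vi])
        order = np.argsort(d)[:3]
        bridge = []
        for k in order:
            a = vi[order[0]]
            b = vi[k]
            c = vj[nearest[k]]
            if a != b:
                bridge.append((a, b, c))
        if not bridge:
            a, c = vi[order[0]], vj[nearest[order[0]]]
            b = vi[(order[0] + 1) % len(vi)]
            bridge.append((a, b, c))
        triangles = np.vstack([triangles, np.asarray(bridge, dtype=np.int64)])
        gt.merged_pairs.append((i, j))

    keep_vertex = np.ones(len(vertices), dtype=bool)
    for li in opts.detach_petiole:
        keep_vertex &= ~labels.petiole_mask(li)
        gt.detached.append(li)

    tri_keep = keep_vertex[triangles].all(axis=1)
    triangles = triangles[tri_keep]

    if opts.hole_fraction > 0 and len(triangles):
        n_remove = int(round(opts.hole_fraction * len(triangles)))
        if n_remove:
            # grow connected triangle patches from random seeds
            tm_adj = _triangle_adjacency(triangles)
            removed = np.zeros(len(triangles), dtype=bool)
            n_patches = max(1, n_remove // 12)
            seeds = rng.choice(len(triangles), size=n_patches, replace=False)
            frontier = list(seeds)
            count = 0
            while frontier and count < n_remove:
                t = frontier.pop(0)
                if removed[t]:
                    continue
                removed[t] = True
                count += 1
                frontier.extend(tm_adj.get(t, ()))
            triangles = triangles[~removed]

    # drop vertices that lost every triangle or were explicitly removed
    referenced = np.zeros(len(vertices), dtype=bool)
    if len(triangles):
        referenced[np.unique(triangles)] = True
    keep = referenced & keep_vertex
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[keep] = np.arange(keep.sum())
    vertices = vertices[keep]
    triangles = remap[triangles]
    if opts.vertex_noise_sd > 0:
        vertices = vertices + rng.normal(0.0, opts.vertex_noise_sd, vertices.shape)
    gt.labels = labels.subset(keep)
    return PlantMesh(vertices, triangles, mesh.up_vector.copy()), gt


def suggest_merge_pair(gt: GroundTruth) -> tuple[int, int]:
    """A realistic leaf pair for the merged-leaves defect: adjacent
    attachments, both blades of near-typical size, smallest azimuthal gap
    (occlusion merges happen between neighbouring leaves of full size)."""
    lp = gt.leaf_params
    med_a = float(lp["area"].median())
    order = lp.sort_values("attachment_height").index.to_list()
    best = None
    for a, b in zip(order[:-1], order[1:]):
        if lp.loc[a, "area"] >= 0.85 * med_a and lp.loc[b, "area"] >= 0.85 * med_a:
            daz = abs(lp.loc[a, "azimuth"] - lp.loc[b, "azimuth"]) % 360.0
            daz = min(daz, 360.0 - daz)
            if best is None or daz < best[2]:
                best = (int(a), int(b), daz)
    if best is None:
        return int(order[0]), int(order[1])
    return best[0], best[1]


def _triangle_adjacency(triangles: np.ndarray) -> dict[int, list[int]]:
    edge_map: dict[tuple[int, int], list[int]] = {}
    for t, tri in enumerate(triangles):
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edge_map.setdefault(key, []).append(t)
    adj: dict[int, list[int]] = {}
    for ts in edge_map.values():
        for t in ts:
            for u in ts:
                if u != t:
                    adj.setdefault(t, []).append(u)
    return adj
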