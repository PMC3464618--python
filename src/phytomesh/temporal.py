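"""Organ tracking across imaging dates.

Consecutive time-points are matched pairwise: the earlier plant is rigidly
aligned to the later one (translation between the lowest stem points plus a
rotation about the stem axis that minimises the sum over leaves of the
distance to the nearest leaf centroid), then leaf correspondence is solved
as a one-to-one assignment on centroid distances, gated by an angular
eligibility window about the stem axis. Petiole pairs mirror leaf pairs;
internodes match by overlap of their normalised-height intervals (an
internode may map to several later ones when a new petiole emerges inside
it). Chaining the pairwise matches over all time-points yields per-organ
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, minimize_scalar

from phytomesh import mesh_core as mc
from phytomesh.config import PipelineConfig
from phytomesh.mesh_core import PlantMesh, SegmentationLabels
from phytomesh.phenotyping import PhenotypeRecord
from phytomesh.segmentation import StemModel

_BIG = 1e9  # finite sentinel for gated-out pairs


@dataclass
class SegmentedPlant:
    """One plant at one time-point, segmented (and optionally measured)."""

    mesh: PlantMesh
    labels: SegmentationLabels
    stem_model: StemModel
    record: PhenotypeRecord | None = None

    def leaf_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        ids = self.labels.leaf_indices
        cents = np.array([
            self.mesh.vertices[self.labels.leaf_mask(i)].mean(axis=0) for i in ids
        ]).reshape(-1, 3)
        return ids, cents


@dataclass
class AlignmentResult:
    translation: np.ndarray  # mm
    angle: float  # deg, rotation about the stem axis
    metric: float  # sum of per-leaf nearest distances at the optimum, mm
    per_leaf_dopt: np.ndarray  # mm, one entry per leaf of the earlier plant


@dataclass
class MatchResult:
    leaf_pairs: list  # [(i at Tx, j at Tx+1)], one-to-one
    petiole_pairs: list  # inherited from leaf pairs
    internode_map: dict  # internode at Tx -> list of internodes at Tx+1
    unmatched_a: list
    unmatched_b: list
    alignment: AlignmentResult | None = None


@dataclass
class OrganTrajectory:
    organ_type: str
    chain: list  # [(timepoint, organ_index)], consecutive time-points
    birth_timepoint: int
    params: pd.DataFrame | None = None  # parameter series where measured


def _rotate_about(points, base, axis, angle_rad):
    rel = points - base
    par = np.outer(rel @ axis, axis)
    perp = rel - par
    cross = np.cross(np.broadcast_to(axis, perp.shape), perp)
    return base + par + np.cos(angle_rad) * perp + np.sin(angle_rad) * cross


def align_plants(
    a: SegmentedPlant, b: SegmentedPlant, config: PipelineConfig | None = None
) -> AlignmentResult:
    """Rigidly align plant ``a`` (earlier) to ``b`` (later).

    Translation: lowest stem point of b minus lowest stem point of a.
    Rotation: exhaustive 1-degree grid about b's stem axis followed by a
    bounded scalar refinement inside the best bracket; the metric at angle
    alpha is the sum over a's leaves of the distance to the nearest leaf
    centroid of b.
    """
    cfg = config or PipelineConfig()
    ids_a, ca = a.leaf_centroids()
    ids_b, cb = b.leaf_centroids()
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("alignment metric undefined: a plant has no leaves")
    translation = b.stem_model.base_point - a.stem_model.base_point
    base = b.stem_model.base_point
    # stems are near-vertical; rotating about the up direction through the
    # stem base is the stable reading of "rotation about the stem axis"
    axis = b.mesh.up_vector
    ca_t = ca + translation

    def metric(angle_deg: float) -> tuple[float, np.ndarray]:
        rot = _rotate_about(ca_t, base, axis, np.deg2rad(angle_deg))
        d = np.linalg.norm(rot[:, None, :] - cb[None, :, :], axis=2).min(axis=1)
        return float(d.sum()), d

    grid = np.arange(0.0, 360.0, cfg.alpha_grid_step)
    values = np.array([metric(g)[0] for g in grid])
    best = int(np.argmin(values))
    lo = grid[best] - cfg.alpha_grid_step
    hi = grid[best] + cfg.alpha_grid_step
    res = minimize_scalar(lambda x: metric(x)[0], bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    alpha = float(res.x % 360.0)
    m, dopt = metric(alpha)
    if values[best] < m:  # keep the grid optimum if refinement did not help
        alpha = float(grid[best])
        m, dopt = metric(alpha)
    return AlignmentResult(translation=translation, angle=alpha, metric=m, per_leaf_dopt=dopt)


def _azimuths(points, base, axis):
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rel = points - base
    return np.degrees(np.arctan2(rel @ e2, rel @ e1)) % 360.0


def match_leaves(
    a: SegmentedPlant,
    b: SegmentedPlant,
    alignment: AlignmentResult,
    gate: float | None = None,
    config: PipelineConfig | None = None,
) -> MatchResult:
    """One-to-one leaf assignment on aligned centroid distances.

    Leaves farther apart than ``gate`` degrees of azimuth about the stem
    axis are ineligible (infinite cost); surplus leaves (growth) stay
    unmatched; petiole pairs are inherited from the leaf pairs.
    """
    cfg = config or PipelineConfig()
    gate = cfg.angular_gate if gate is None else gate
    ids_a, ca = a.leaf_centroids()
    ids_b, cb = b.leaf_centroids()
    base, axis = b.stem_model.base_point, b.mesh.up_vector
    ca_al = _rotate_about(ca + alignment.translation, base, axis, np.deg2rad(alignment.angle))
    cost = np.linalg.norm(ca_al[:, None, :] - cb[None, :, :], axis=2)
    az_a = _azimuths(ca_al, base, axis)
    az_b = _azimuths(cb, base, axis)
    dphi = np.abs(az_a[:, None] - az_b[None, :])
    dphi = np.minimum(dphi, 360.0 - dphi)
    cost = np.where(dphi <= gate, cost, _BIG)
    # square the matrix with the sentinel so the solver sees explicit padding
    n = max(len(ids_a), len(ids_b))
    padded = np.full((n, n), _BIG)
    padded[: len(ids_a), : len(ids_b)] = cost
    rows, cols = linear_sum_assignment(padded)
    pairs = []
    for r, c in zip(rows, cols):
        if r < len(ids_a) and c < len(ids_b) and padded[r, c] < _BIG / 2:
            pairs.append((int(ids_a[r]), int(ids_b[c])))
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    pet_a = set(a.labels.petiole_indices)
    pet_b = set(b.labels.petiole_indices)
    pet_pairs = [(i, j) for i, j in pairs if i in pet_a and j in pet_b]
    return MatchResult(
        leaf_pairs=pairs,
        petiole_pairs=pet_pairs,
        internode_map=match_internodes(a, b),
        unmatched_a=[int(i) for i in ids_a if i not in matched_a],
        unmatched_b=[int(j) for j in ids_b if j not in matched_b],
        alignment=alignment,
    )


def match_internodes(a: SegmentedPlant, b: SegmentedPlant) -> dict:
    """Internode a_k -> internodes of b whose normalised-height intervals
    overlap (open overlap: a zero-length touch is not a match)."""
    ia = a.stem_model.internode_intervals
    ib = b.stem_model.internode_intervals
    out: dict[int, list[int]] = {}
    for k, (lo_a, hi_a) in enumerate(ia):
        out[k] = [
            m for m, (lo_b, hi_b) in enumerate(ib) if lo_a < hi_b and lo_b < hi_a
        ]
    return out


def pairwise_match_sequence(
    plants: list[SegmentedPlant], config: PipelineConfig | None = None
) -> list[MatchResult | None]:
    """Match every consecutive pair; a failing pair yields None and the
    sequence continues."""
    cfg = config or PipelineConfig()
    out = []
    for a, b in zip(plants[:-1], plants[1:]):
        try:
            al = align_plants(a, b, cfg)
            out.append(match_leaves(a, b, al, config=cfg))
        except ValueError:
            out.append(None)
    return out


def track_sequence(
    plants: list[SegmentedPlant], config: PipelineConfig | None = None
) -> list[OrganTrajectory]:
    """Chain the pairwise matches into per-organ trajectories.

    An organ unmatched at a step terminates its chain; organs appearing
    later start new chains; a never-matched organ still yields a length-1
    trajectory. Leaf parameter series are attached from the plants'
    phenotype records where available.
    """
    if len(plants) < 2:
        raise ValueError("need at least two time-points")
    cfg = config or PipelineConfig()
    matches = pairwise_match_sequence(plants, cfg)
    trajectories: list[OrganTrajectory] = []
    open_chains: dict[int, OrganTrajectory] = {}  # leaf index at current t -> traj

    for t, plant in enumerate(plants):
        ids = [int(i) for i in plant.labels.leaf_indices]
        next_open: dict[int, OrganTrajectory] = {}
        for i in ids:
            if i in open_chains:
                traj = open_chains[i]
            else:
                traj = OrganTrajectory(organ_type="leaf", chain=[], birth_timepoint=t)
                trajectories.append(traj)
            traj.chain.append((t, i))
            if t < len(matches) and matches[t] is not None:
                for ai, bj in matches[t].leaf_pairs:
                    if ai == i:
                        next_open[bj] = traj
                        break
        open_chains = next_open

    # attach parameter series
    for traj in trajectories:
        rows = []
        for t, i in traj.chain:
            rec = plants[t].record
            if rec is not None and i in rec.leaves.index:
                r = rec.leaves.loc[i]
                rows.append(dict(timepoint=t, organ_index=i, width=r["width"],
                                 length=r["length"], area=r["area"],
                                 thickness=r["thickness"], inclination=r["inclination"]))
        if rows:
            traj.params = pd.DataFrame(rows)
    return trajectories


def trajectories_to_table(trajectories: list[OrganTrajectory]) -> pd.DataFrame:
    rows = []
    for tid, traj in enumerate(trajectories):
        for t, i in traj.chain:
            row = dict(trajectory_id=tid, organ_type=traj.organ_type,
                       timepoint=t, organ_index=i)
            if traj.params is not None:
                sel = traj.params[traj.params["timepoint"] == t]
                if len(sel):
                    for col in ("width", "length", "area", "thickness", "inclination"):
                        row[col] = float(sel.iloc[0][col])
            rows.append(row)
    return pd.DataFrame(rows)
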