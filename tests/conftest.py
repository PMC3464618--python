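import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from phytomesh import default_spec, generate_plant
from phytomesh.mesh_core import PlantMesh
from phytomesh.segmentation import segment_plant


@pytest.fixture(scope="session")
def plant_seed1():
    """Default plant, seed 1: (mesh, ground truth)."""
    return generate_plant(default_spec(1))


@pytest.fixture(scope="session")
def segmented_seed1(plant_seed1):
    mesh, gt = plant_seed1
    return mesh, gt, segment_plant(mesh)


@pytest.fixture
def flat_grid():
    """Flat 5x5 unit grid in the z=0 plane."""
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(25)])
    tris = []
    for i in range(4):
        for j in range(4):
            a, b, c, d = i * 5 + j, i * 5 + j + 1, (i + 1) * 5 + j, (i + 1) * 5 + j + 1
            tris.append((a, b, c))
            tris.append((b, d, c))
    return PlantMesh(verts, np.asarray(tris))


def leaf_index_map(mesh, labels, gt):
    """Predicted leaf index -> ground-truth leaf index, by centroid assignment."""
    pred_ids = labels.leaf_indices
    gt_ids = gt.labels.leaf_indices
    if len(pred_ids) == 0 or len(gt_ids) == 0:
        return {}
    pc = np.array([mesh.vertices[labels.leaf_mask(i)].mean(axis=0) for i in pred_ids])
    gc = np.array([mesh.vertices[gt.labels.leaf_mask(i)].mean(axis=0) for i in gt_ids])
    rows, cols = linear_sum_assignment(np.linalg.norm(pc[:, None] - gc[None, :], axis=2))
    return {int(pred_ids[r]): int(gt_ids[c]) for r, c in zip(rows, cols)}


def rotation_about_z(deg):
    a = np.deg2rad(deg)
    return np.array([
        [np.cos(a), -np.sin(a), 0.0],
        [np.sin(a), np.cos(a), 0.0],
        [0.0, 0.0, 1.0],
    ])
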