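import numpy as np
import pandas as pd
import pytest
from conftest import leaf_index_map, rotation_about_z

from phytomesh import default_spec, generate_plant
from phytomesh import mesh_core as mc
from phytomesh.config import PipelineConfig
from phytomesh.mesh_core import Curve3D, PlantMesh, SegmentationLabels
from phytomesh.phenotyping import (
    PhenotypeRecord,
    extract_phenotypes,
    leaf_area,
    leaf_frame,
    leaf_inclination,
    leaf_thickness,
    leaf_width_length,
    petiole_metrics,
    stem_metrics,
)
from phytomesh.segmentation import StemModel, segment_plant
from phytomesh.synthetic_plants import LeafSpec, PlantSpec


def bare_cylinder(axis_dir, length=100.0, radius=3.0, n_theta=12, n_axial=30):
    """Hand-built stem mesh + all-stem labels + matching stem model."""
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    ref = np.array([1.0, 0, 0]) if abs(axis_dir[0]) < 0.9 else np.array([0.0, 1, 0])
    e1 = np.cross(axis_dir, ref); e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_dir, e1)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    ring = radius * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
    verts = []
    for s in np.linspace(0, length, n_axial + 1):
        verts.extend(s * axis_dir + ring)
    verts = np.asarray(verts)
    tris = []
    for i in range(n_axial):
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            a, b = i * n_theta + j, i * n_theta + jn
            c, d = (i + 1) * n_theta + j, (i + 1) * n_theta + jn
            tris += [(a, c, b), (b, c, d)]
    mesh = PlantMesh(verts, np.asarray(tris))
    labels = SegmentationLabels.empty(mesh.n_vertices)
    labels.organ[:] = mc.STEM
    labels.index[:] = 0
    curve = Curve3D([np.zeros(3), length * axis_dir])
    lo = verts[np.argmin(verts @ mesh.up_vector)]
    model = StemModel(curve=curve, axis=axis_dir, radius=radius,
                      junction_heights=np.array([]), base_point=lo)
    return mesh, labels, model


def single_leaf_plant(**kw):
    defaults = dict(attachment_height=100.0, azimuth=0.0, petiole_length=45.0,
                    petiole_initiation_angle=60.0, leaf_width=80.0,
                    leaf_length=100.0, leaf_inclination=90.0, blade_bend=0.0)
    defaults.update(kw)
    spec = PlantSpec(leaves=[LeafSpec(**defaults)])
    mesh, gt = generate_plant(spec)
    res = segment_plant(mesh)
    return mesh, gt, res


class TestStemMetrics:
    def test_vertical_stem(self):
        mesh, labels, model = bare_cylinder([0, 0, 1.0], length=170.0)
        h, ln, inc = stem_metrics(mesh, labels, model)
        assert h == pytest.approx(170.0, abs=2.0)
        assert inc == pytest.approx(0.0, abs=1.0)

    def test_tilted_45_degrees(self):
        # thin tube so the surface does not extend the vertical span
        d = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        mesh, labels, model = bare_cylinder(d, length=100.0, radius=0.3)
        h, ln, inc = stem_metrics(mesh, labels, model)
        assert h == pytest.approx(70.7, abs=2.0)
        assert inc == pytest.approx(45.0, abs=2.0)
        assert ln == pytest.approx(100.0, abs=1.0)

    def test_length_at_least_height(self):
        mesh, gt = generate_plant(default_spec(5))
        res = segment_plant(mesh)
        h, ln, _ = stem_metrics(mesh, res.labels, res.stem_model)
        assert ln >= h - 1e-6

    def test_empty_stem_is_an_error(self):
        mesh, labels, model = bare_cylinder([0, 0, 1.0])
        labels.organ[:] = mc.LEAF
        with pytest.raises(ValueError):
            stem_metrics(mesh, labels, model)


class TestPetioleMetrics:
    def test_horizontal_petiole(self):
        mesh, gt, res = single_leaf_plant(petiole_initiation_angle=90.0,
                                          petiole_length=40.0)
        length, alpha = petiole_metrics(mesh, res.labels, res.stem_model, 0)
        assert length == pytest.approx(40.0, abs=2.0)
        assert alpha == pytest.approx(90.0, abs=3.0)

    def test_steep_petiole_small_angle(self):
        # petioles rising nearly parallel to the stem give small angles;
        # below ~25 deg they start to hide inside the coarse stem band
        mesh, gt, res = single_leaf_plant(petiole_initiation_angle=30.0,
                                          leaf_inclination=60.0)
        _, alpha = petiole_metrics(mesh, res.labels, res.stem_model, 0)
        assert alpha == pytest.approx(30.0, abs=6.0)

    def test_missing_petiole_reports_na_not_zero(self):
        mesh, labels, model = bare_cylinder([0, 0, 1.0])
        length, alpha = petiole_metrics(mesh, labels, model, 5)
        assert np.isnan(length) and np.isnan(alpha)


class TestLeafFrame:
    def test_extreme_points_on_flat_blade(self):
        mesh, gt, res = single_leaf_plant()
        fr = leaf_frame(mesh, res.labels, 0, res.stem_model)
        # S points are the lateral extremes of the blade (x = +-40 here)
        sx = sorted([mesh.vertices[fr.S1][0], mesh.vertices[fr.S2][0]])
        assert sx[0] == pytest.approx(-40.0, abs=2.0)
        assert sx[1] == pytest.approx(40.0, abs=2.0)
        # C2 is the apex (farthest along the midrib), C1 near the base
        assert mesh.vertices[fr.C2][1] > mesh.vertices[fr.C1][1] + 90.0

    def test_s_points_on_opposite_sides(self):
        mesh, gt, res = single_leaf_plant()
        fr = leaf_frame(mesh, res.labels, 0, res.stem_model)
        s1 = (mesh.vertices[fr.S1] - fr.centroid) @ fr.u1
        s2 = (mesh.vertices[fr.S2] - fr.centroid) @ fr.u1
        assert s1 * s2 < 0

    def test_rotation_equivariance_of_frame_vectors(self):
        mesh, gt, res = single_leaf_plant()
        fr = leaf_frame(mesh, res.labels, 0, res.stem_model)
        R = rotation_about_z(40.0)
        moved = mesh.transformed(rotation=R)
        res2 = segment_plant(moved)
        m = leaf_index_map(moved, res2.labels, gt)  # single leaf, index may shift
        li = list(res2.labels.leaf_indices)[0]
        fr2 = leaf_frame(moved, res2.labels, li, res2.stem_model)
        np.testing.assert_allclose(np.abs(fr2.u2 @ (R @ fr.u2)), 1.0, atol=0.02)

    def test_one_side_empty_is_an_error(self):
        mesh, gt, res = single_leaf_plant()
        labels = res.labels.copy()
        leaf = labels.leaf_mask(0)
        labels.side[leaf] = mc.SIDE_LEFT
        with pytest.raises(ValueError):
            leaf_frame(mesh, labels, 0, res.stem_model)


class TestWidthLength:
    def test_flat_blade_dimensions(self):
        mesh, gt, res = single_leaf_plant()
        fr = leaf_frame(mesh, res.labels, 0, res.stem_model)
        w, ln, flag = leaf_width_length(mesh, res.labels, 0, fr)
        assert w == pytest.approx(80.0, abs=3.0)
        assert ln == pytest.approx(100.0, abs=3.0)
        assert flag == ""

    def test_bent_blade_keeps_developed_length(self):
        mesh, gt, res = single_leaf_plant(blade_bend=1.0)
        fr = leaf_frame(mesh, res.labels, 0, res.stem_model)
        _, ln, _ = leaf_width_length(mesh, res.labels, 0, fr)
        assert ln == pytest.approx(100.0, abs=5.0)
        # and the chord is clearly shorter than the developed length
        chord = np.linalg.norm(mesh.vertices[fr.C2] - mesh.vertices[fr.C1])
        assert chord < 0.97 * ln

    def test_scaling_homogeneity(self):
        mesh, gt, res = single_leaf_plant()
        fr = leaf_frame(mesh, res.labels, 0, res.stem_model)
        w1, l1, _ = leaf_width_length(mesh, res.labels, 0, fr)
        scaled = PlantMesh(mesh.vertices * 2.0, mesh.triangles.copy())
        fr2 = leaf_frame(scaled, res.labels, 0, _scaled_model(res.stem_model, 2.0))
        w2, l2, _ = leaf_width_length(scaled, res.labels, 0, fr2)
        assert w2 == pytest.approx(2 * w1, rel=1e-6)
        assert l2 == pytest.approx(2 * l1, rel=1e-6)


def _scaled_model(model, s):
    return StemModel(curve=Curve3D(model.curve.points * s), axis=model.axis,
                     radius=model.radius * s, junction_heights=model.junction_heights,
                     base_point=model.base_point * s)


class TestAreaThickness:
    def test_two_parallel_rectangles(self):
        # 80 x 100 sheets, 2 mm apart -> area 8000, thickness 2
        xs, ys = np.meshgrid(np.linspace(0, 80, 9), np.linspace(0, 100, 11))
        def sheet(z):
            verts = np.column_stack([xs.ravel(), ys.ravel(), np.full(99, z)])
            tris = []
            for i in range(10):
                for j in range(8):
                    a, b = i * 9 + j, i * 9 + j + 1
                    c, d = (i + 1) * 9 + j, (i + 1) * 9 + j + 1
                    tris += [(a, b, c), (b, d, c)]
            return verts, np.asarray(tris)
        v1, t1 = sheet(0.0)
        v2, t2 = sheet(2.0)
        mesh = PlantMesh(np.vstack([v1, v2]), np.vstack([t1[:, ::-1], t2 + 99]))
        labels = SegmentationLabels.empty(mesh.n_vertices)
        labels.organ[:] = mc.LEAF
        labels.index[:] = 0
        labels.surface[:99] = mc.SURFACE_ABAXIAL
        labels.surface[99:] = mc.SURFACE_ADAXIAL
        area, two = leaf_area(mesh, labels, 0)
        assert two
        assert area == pytest.approx(8000.0, rel=1e-6)
        th = leaf_thickness(mesh, labels, 0)
        assert th == pytest.approx(2.0, abs=0.01)

    def test_lobed_blade_area_vs_ground_truth(self):
        mesh, gt, res = single_leaf_plant()
        area, _ = leaf_area(mesh, res.labels, 0)
        assert area == pytest.approx(gt.leaf_params.loc[0, "area"], rel=0.05)

    def test_area_rigid_motion_invariant(self):
        mesh, gt, res = single_leaf_plant()
        a1, _ = leaf_area(mesh, res.labels, 0)
        moved = mesh.transformed(rotation=rotation_about_z(33.0), translation=np.array([5, 6, 7.0]))
        a2, _ = leaf_area(moved, res.labels, 0)
        assert a2 == pytest.approx(a1, rel=1e-6)

    def test_thickness_direction_asymmetry_small(self):
        mesh, gt, res = single_leaf_plant()
        labels = res.labels
        # swap surface labels to compute the reverse direction
        swapped = labels.copy()
        leaf = labels.leaf_mask(0)
        swapped.surface[leaf] = np.where(
            labels.surface[leaf] == mc.SURFACE_ADAXIAL, mc.SURFACE_ABAXIAL, mc.SURFACE_ADAXIAL
        )
        t1 = leaf_thickness(mesh, labels, 0)
        t2 = leaf_thickness(mesh, swapped, 0)
        assert abs(t1 - t2) / t1 < 0.10

    def test_thickness_scales_linearly(self):
        mesh, gt, res = single_leaf_plant()
        t1 = leaf_thickness(mesh, res.labels, 0)
        scaled = PlantMesh(mesh.vertices * 3.0, mesh.triangles.copy())
        t2 = leaf_thickness(scaled, res.labels, 0)
        assert t2 == pytest.approx(3 * t1, rel=1e-9)


class TestInclination:
    def test_horizontal_leaf_on_vertical_stem(self):
        mesh, gt, res = single_leaf_plant(leaf_inclination=90.0)
        fr = leaf_frame(mesh, res.labels, 0, res.stem_model)
        inc = leaf_inclination(fr, res.stem_model.axis, mesh)
        assert inc == pytest.approx(90.0, abs=3.0)

    def test_generated_inclination_recovered(self):
        mesh, gt, res = single_leaf_plant(leaf_inclination=30.0, azimuth=200.0)
        fr = leaf_frame(mesh, res.labels, 0, res.stem_model)
        inc = leaf_inclination(fr, res.stem_model.axis, mesh)
        assert inc == pytest.approx(gt.leaf_params.loc[0, "inclination"], abs=5.0)

    def test_invariant_to_rotation_about_stem(self):
        mesh, gt, res = single_leaf_plant(leaf_inclination=60.0)
        fr = leaf_frame(mesh, res.labels, 0, res.stem_model)
        inc1 = leaf_inclination(fr, res.stem_model.axis, mesh)
        moved = mesh.transformed(rotation=rotation_about_z(120.0))
        res2 = segment_plant(moved)
        li = list(res2.labels.leaf_indices)[0]
        fr2 = leaf_frame(moved, res2.labels, li, res2.stem_model)
        inc2 = leaf_inclination(fr2, res2.stem_model.axis, moved)
        assert inc2 == pytest.approx(inc1, abs=2.0)


class TestExtractPhenotypes:
    def test_full_record_and_csv_round_trip(self, tmp_path, segmented_seed1):
        mesh, gt, res = segmented_seed1
        rec = extract_phenotypes(mesh, res.labels, res.stem_model, mesh_id="p1")
        assert rec.n_leaves == gt.labels.n_leaves
        path = tmp_path / "phen.csv"
        rec.save_csv(path)
        back = pd.read_csv(path)
        long = rec.to_long()
        np.testing.assert_allclose(back["value"], long["value"], rtol=1e-12)
        for col in ("plant", "timepoint", "organ_type", "organ_index"):
            assert (back[col].astype(str) == long[col].astype(str)).all()

    def test_detached_petiole_gives_empty_cells_not_zero(self, tmp_path, plant_seed1):
        from phytomesh import DefectOptions, perturb_mesh

        mesh, gt = plant_seed1
        pm, pgt = perturb_mesh(mesh, gt, DefectOptions(detach_petiole=(0,)), seed=0)
        res = segment_plant(pm)
        rec = extract_phenotypes(pm, res.labels, res.stem_model)
        assert rec.petioles["length"].isna().sum() >= 1
        assert not (rec.petioles["length"] == 0).any()
        path = tmp_path / "phen.csv"
        rec.save_csv(path)
        text = path.read_text()
        assert ",," in text  # NA serialises as an empty cell

    def test_config_hash_tracks_thresholds(self, segmented_seed1):
        mesh, _, res = segmented_seed1
        r1 = extract_phenotypes(mesh, res.labels, res.stem_model, PipelineConfig())
        r2 = extract_phenotypes(
            mesh, res.labels, res.stem_model, PipelineConfig(merged_leaf_tau=2.0)
        )
        assert r1.provenance["config_hash"] != r2.provenance["config_hash"]
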