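import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from femaxis.exceptions import (
    DegenerateLandmarksError,
    HeadNotFoundError,
    StackTruncatedError,
    UndefinedRotationError,
)
from femaxis.geometry import (
    Line3D,
    Plane,
    angle_between_lines,
    point_line_distance,
    points_line_distance,
)
from femaxis.model import (
    FemoralNeckAxisModel,
    LandmarkSet,
    SectionConfig,
    build_section_stack,
    deviated_axis,
    initial_plane,
    select_head_vertices,
)
from femaxis.synthetic import FemurSpec, generate_femur


class TestLandmarkSet:
    def test_collinear_rejected(self):
        with pytest.raises(DegenerateLandmarksError):
            LandmarkSet((0, 0, 0), (1, 0, 0), (2, 0, 0), (0, 0, 5))

    def test_head_hint_on_plane_rejected(self):
        with pytest.raises(DegenerateLandmarksError):
            LandmarkSet((0, 0, 0), (10, 0, 0), (0, 10, 0), (3, 3, 0))


class TestInitialPlane:
    def test_through_landmarks_toward_head(self):
        lm = LandmarkSet((0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, 30))
        plane = initial_plane(lm)
        np.testing.assert_allclose(plane.normal, (0, 0, 1), atol=1e-12)
        assert abs(plane.signed_distance(np.zeros(3))) < 1e-12

    def test_orientation_flips_with_hint(self):
        lm = LandmarkSet((0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, -30))
        np.testing.assert_allclose(initial_plane(lm).normal, (0, 0, -1), atol=1e-12)

    def test_synthetic_normal_points_along_true_axis(self, default_femur):
        _, truth = default_femur
        plane = initial_plane(truth.landmarks)
        assert plane.normal @ truth.neck_axis.direction > 0


def tube(radius=15.0, height=60.0, tilt_deg=0.0):
    mesh = trimesh.creation.cylinder(radius=radius, height=height, sections=128)
    mesh.apply_translation((0, 0, height / 2))  # base at z=0
    if tilt_deg:
        mesh.apply_transform(
            trimesh.transformations.rotation_matrix(
                np.radians(tilt_deg), (1, 0, 0), (0, 0, 0)
            )
        )
    return mesh


class TestBuildSectionStack:
    def test_ideal_cylinder_centroids_on_axis(self):
        mesh = tube()
        stack = build_section_stack(
            mesh, Plane((0, 0, 0), (0, 0, 1)), SectionConfig(), (0, 0, 1)
        )
        assert len(stack) == 10
        cents = np.array([c for _, c in stack])
        np.testing.assert_allclose(cents[:, :2], 0.0, atol=1e-9)
        np.testing.assert_allclose(cents[:, 2], np.arange(1, 11), atol=1e-9)

    def test_tilted_cylinder_centroids_collinear(self):
        mesh = tube(tilt_deg=30.0)
        axis_dir = np.array([0.0, -np.sin(np.radians(30)), np.cos(np.radians(30))])
        stack = build_section_stack(
            mesh, Plane((0, 0, 0), axis_dir), SectionConfig(), axis_dir
        )
        cents = np.array([c for _, c in stack])
        line = Line3D((0, 0, 0), axis_dir)
        assert np.max(points_line_distance(cents, line)) < 1e-9

    def test_synthetic_centroids_near_true_axis(self, default_femur):
        mesh, truth = default_femur
        lm = truth.landmarks
        base = initial_plane(lm)
        ref = lm.head_hint - base.signed_distance(lm.head_hint) * base.normal
        stack = build_section_stack(mesh, base, SectionConfig(), ref)
        cents = np.array([c for _, c in stack])
        assert np.max(points_line_distance(cents, truth.neck_axis)) < 2.0

    def test_truncation_is_fatal_below_three_sections(self):
        short = tube(height=2.5)
        with pytest.raises(StackTruncatedError) as exc:
            build_section_stack(
                short, Plane((0, 0, 0), (0, 0, 1)), SectionConfig(), (0, 0, 1)
            )
        assert exc.value.n_ok == 2


class TestFitPipeline:
    def test_ideal_femur_recovers_axis_and_dbhf(self, default_fit):
        res, truth = default_fit
        assert res.angle_to(truth.neck_axis) <= 1.0
        assert res.dbhf <= 0.3

    def test_head_sphere_recovers_centre_and_radius(self, default_fit):
        res, truth = default_fit
        assert np.linalg.norm(res.head_sphere.centre - truth.head_centre) < 0.5
        assert res.head_sphere.radius == pytest.approx(24.0, abs=0.5)

    def test_dbhf_equals_head_to_axis_distance(self, default_fit):
        res, _ = default_fit
        assert res.dbhf == pytest.approx(
            point_line_distance(res.head_sphere.centre, res.fna), abs=1e-9
        )

    def test_records_one_axis_per_iteration(self, default_fit):
        res, _ = default_fit
        assert len(res.per_iteration_axes) == res.config.n_iterations
        assert len(res.centroids) == res.config.n_iterations
        assert all(c.shape == (10, 3) for c in res.centroids)

    def test_offset_head_recovered_within_half_mm(self):
        mesh, truth = generate_femur(FemurSpec(head_offset=3.0))
        res = FemoralNeckAxisModel(mesh, truth.landmarks).fit()
        assert 2.5 <= res.dbhf <= 3.5

    def test_rigid_equivariance(self, default_femur, default_fit, rng):
        mesh, truth = default_femur
        res0, _ = default_fit
        R = Rotation.random(random_state=11).as_matrix()
        t = rng.uniform(-40, 40, 3)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = t
        m2 = mesh.copy()
        m2.apply_transform(M)
        res2 = FemoralNeckAxisModel(m2, truth.landmarks.transformed(M)).fit()
        back = Line3D(R.T @ (res2.fna.point - t), R.T @ res2.fna.direction)
        assert angle_between_lines(back, res0.fna) <= 0.1
        assert point_line_distance(res0.fna.point, back) <= 0.05

    def test_early_stop_runs_fewer_iterations(self, default_femur):
        mesh, truth = default_femur
        cfg = SectionConfig(early_stop_tol_deg=5.0)
        res = FemoralNeckAxisModel(mesh, truth.landmarks, cfg).fit()
        assert len(res.per_iteration_axes) < cfg.n_iterations

    def test_contour_source_cylinder_has_neck_radius(self, default_femur):
        mesh, truth = default_femur
        cfg = SectionConfig(cylinder_source="contours")
        res = FemoralNeckAxisModel(mesh, truth.landmarks, cfg).fit()
        assert 10.0 < res.cylinder.radius < 20.0

    def test_summary_and_serialisation(self, default_fit):
        res, _ = default_fit
        text = res.summary()
        assert "DBHF" in text and "FNA direction" in text
        doc = res.to_dict()
        assert set(doc) >= {"fna", "cylinder", "head_sphere", "dbhf_mm"}
        np.testing.assert_allclose(doc["fna"]["direction"], res.fna.direction)


class TestSelectHeadVertices:
    def test_selection_matches_generator_tags(self, default_femur, default_fit):
        mesh, truth = default_femur
        res, _ = default_fit
        t_last = float(
            (res.centroids[-1][-1] - res.fna.point) @ res.fna.direction
        )
        sel = select_head_vertices(mesh, res.fna, t_min=t_last + 14.0)
        verts = mesh.vertices.view(np.ndarray)
        tagged = verts[truth.head_vertex_tags]
        # selected set covers >= 90% of the tagged head cap beyond the neck
        t_tag = (tagged - res.fna.point) @ res.fna.direction
        reachable = tagged[t_tag > t_last + 14.0]
        sel_set = {tuple(v) for v in np.round(sel, 6)}
        covered = sum(tuple(v) in sel_set for v in np.round(reachable, 6))
        assert covered / len(reachable) >= 0.9
        # and selected vertices lie on the head sphere (<= 5% off-sphere)
        r = np.linalg.norm(sel - truth.head_centre, axis=1)
        assert np.mean(np.abs(r - 24.0) > 0.5) <= 0.05

    def test_headless_mesh_raises(self):
        mesh = tube()
        with pytest.raises(HeadNotFoundError):
            select_head_vertices(mesh, Line3D((0, 0, 0), (0, 0, 1)), t_min=100.0)


class TestDeviatedAxis:
    def test_zero_angle_is_identity(self):
        fna = Line3D((1, 2, 3), (0, 0, 1))
        out = deviated_axis(fna, 0.0, (1, 0, 0))
        np.testing.assert_allclose(out.direction, fna.direction, atol=1e-12)

    def test_twenty_degree_closed_form(self):
        fna = Line3D((0, 0, 0), (0, 0, 1))
        out = deviated_axis(fna, 20.0, (1, 0, 0))
        s, c = np.sin(np.radians(20)), np.cos(np.radians(20))
        # right-hand rotation of +z about +x tips the axis toward -y
        np.testing.assert_allclose(out.direction, (0, -s, c), atol=1e-12)
        assert angle_between_lines(fna, out) == pytest.approx(20.0, abs=1e-9)

    def test_deviation_scenario_on_fitted_axis(self, default_fit):
        # the mis-determined-axis scenario: rotate the fitted FNA by 20 deg
        res, _ = default_fit
        normal = np.cross(res.fna.direction, (0, 0, 1))
        out = deviated_axis(res.fna, 20.0, normal)
        assert angle_between_lines(res.fna, out) == pytest.approx(20.0, abs=1e-9)
        np.testing.assert_allclose(out.point, res.fna.point)

    def test_parallel_normal_rejected(self):
        fna = Line3D((0, 0, 0), (0, 0, 1))
        with pytest.raises(UndefinedRotationError):
            deviated_axis(fna, 20.0, (0, 0, -1))

    def test_large_angle_rejected(self):
        with pytest.raises(ValueError):
            deviated_axis(Line3D((0, 0, 0), (0, 0, 1)), 95.0, (1, 0, 0))
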