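import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spineplan.camera import project_points
from spineplan.geometry import point_segment_distance
from spineplan.mesh import LANDMARK_NAMES, LabeledMesh, REGIONS
from spineplan.planning import (BREACH_THRESHOLD_MM, PATH_DIAMETER_MM, PathPlan,
                                PathTemplate, PlanningFailure, annotate_template_paths,
                                breach_check, geoplan_triangulate, plan_success,
                                propagate_path)
from spineplan.ssm import PoseShapeParams, instantiate


def _tube_mesh(radius, length=20.0, n_theta=720, n_z=11, side="left"):
    """Open cylinder of given radius around the z axis, all vertices labeled
    as one pedicle wall. Dense angular resolution keeps the chordal radius
    deficit below 1e-4 mm so wall distances are analytic to that accuracy."""
    th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(0.0, length, n_z)
    ring = np.column_stack([radius * np.cos(th), radius * np.sin(th)])
    verts = np.concatenate([np.column_stack([ring, np.full(n_theta, z)]) for z in zs])
    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            faces.append([a, b, b + n_theta])
            faces.append([a, b + n_theta, a + n_theta])
    labels = np.full(len(verts), REGIONS.index(f"pedicle_{side}"), dtype=int)
    lm = {name: i for i, name in enumerate(LANDMARK_NAMES)}
    return LabeledMesh(verts, np.asarray(faces, dtype=int), labels, lm)


class TestBreachCheck:
    def test_centered_path_in_radius4_tube_no_breach(self):
        tube = _tube_mesh(4.0)
        plan = PathPlan("left", np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 20.0]))
        plan = breach_check(plan, tube)
        assert abs(plan.min_wall_distance_mm - 4.0) < 1e-3
        assert plan.breach is False
        assert plan.ok

    def test_offset_path_distance_2_breach(self):
        tube = _tube_mesh(4.0)
        plan = PathPlan("left", np.array([2.0, 0.0, 0.0]), np.array([2.0, 0.0, 20.0]))
        plan = breach_check(plan, tube, samples_per_mm2=40.0)
        assert abs(plan.min_wall_distance_mm - 2.0) < 0.05
        assert plan.breach is True
        assert not plan.ok

    def test_verdict_flips_at_threshold(self):
        """Offsets 1.5 ∓ 0.02 in a radius-4 tube put the axis-to-wall distance
        at 2.5 ± 0.02 mm: the verdict must flip across 2.5 mm exactly."""
        tube = _tube_mesh(4.0)
        for offset, expect_breach in ((1.48, False), (1.52, True)):
            plan = PathPlan("left", np.array([offset, 0.0, 0.0]),
                            np.array([offset, 0.0, 20.0]))
            plan = breach_check(plan, tube, samples_per_mm2=40.0)
            assert plan.breach is expect_breach, (offset, plan.min_wall_distance_mm)
        # and the threshold itself is the documented constant
        assert BREACH_THRESHOLD_MM == 2.5
        assert PATH_DIAMETER_MM == 5.0

    def test_matches_dense_brute_force_oracle(self, phantom, phantom_axes):
        p0, p1 = phantom_axes["left"]
        plan = breach_check(PathPlan("left", p0, p1), phantom, samples_per_mm2=10.0)
        # oracle: exhaustive distance over a very dense independent sample of
        # the same wall region (vertices + high-rate area-weighted samples)
        label = REGIONS.index("pedicle_left")
        vmask = phantom.region_labels == label
        fmask = vmask[phantom.faces].sum(axis=1) >= 2
        from spineplan.geometry import sample_surface
        rng = np.random.default_rng(99)
        dense, _ = sample_surface(phantom.vertices, phantom.faces[fmask], 200_000, rng)
        wall = np.vstack([phantom.vertices[vmask], dense])
        oracle = point_segment_distance(wall, p0, p1).min()
        assert abs(plan.min_wall_distance_mm - oracle) < 0.05

    def test_missing_region_raises(self):
        tube = _tube_mesh(4.0, side="left")
        with pytest.raises(ValueError):
            breach_check(PathPlan("right", np.zeros(3), np.array([0, 0, 20.0])), tube)

    def test_deterministic(self):
        tube = _tube_mesh(4.0, n_theta=90)
        mk = lambda: breach_check(
            PathPlan("left", np.array([1.0, 0.5, 2.0]), np.array([0.5, -1.0, 18.0])),
            tube, seed=5)
        assert mk().min_wall_distance_mm == mk().min_wall_distance_mm


class TestPathPlan:
    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            PathPlan("left", np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            PathPlan("left", np.zeros(3), np.ones(3), diameter_mm=0.0)

    def test_dict_roundtrip_fields(self):
        p = PathPlan("right", np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        d = p.to_dict()
        assert d["side"] == "right" and d["diameter_mm"] == 5.0
        assert d["breach"] is None and d["min_wall_distance_mm"] is None


class TestPathTemplate:
    def test_roundtrip(self):
        t = PathTemplate("left", 3, np.array([0.2, 0.3, 0.5]), 7,
                         np.array([1.0, 0.0, 0.0]))
        back = PathTemplate.from_dict(t.to_dict())
        assert back.side == t.side
        assert back.entry_face == 3 and back.exit_face == 7
        assert np.allclose(back.entry_bary, t.entry_bary)
        assert np.allclose(back.exit_bary, t.exit_bary)

    def test_validation(self):
        good = np.array([0.2, 0.3, 0.5])
        with pytest.raises(ValueError):
            PathTemplate("up", 0, good, 1, good)
        with pytest.raises(ValueError):
            PathTemplate("left", 0, np.array([0.5, 0.6, 0.5]), 1, good)
        with pytest.raises(ValueError):
            PathTemplate("left", 0, np.array([-0.2, 0.7, 0.5]), 1, good)

    def test_from_points_anchors_to_surface(self, phantom, phantom_axes):
        p0, p1 = phantom_axes["left"]
        t = PathTemplate.from_points(phantom, "left", p0, p1)
        e, x = t.evaluate(phantom.vertices, phantom.faces)
        # anchored points are the surface projections of the analytic endpoints
        from spineplan.geometry import MeshProximity
        q, _, _ = MeshProximity(phantom.vertices, phantom.faces).closest(
            np.vstack([p0, p1]))
        assert np.allclose(e, q[0], atol=1e-9)
        assert np.allclose(x, q[1], atol=1e-9)

    def test_annotate_template_paths_sides(self, phantom, phantom_axes):
        paths = annotate_template_paths(phantom, phantom_axes)
        assert [p.side for p in paths] == ["left", "right"]


class TestPropagatePath:
    def test_rigid_equivariance(self, small_model):
        """Instance paths must move rigidly with the pose: entry/exit under
        (R, t) equal R @ entry/exit(identity) + t, exactly."""
        model, _ = small_model
        assert model.path_annotations, "model fixture must carry path annotations"
        rng = np.random.default_rng(11)
        coeffs = np.clip(rng.standard_normal(model.n_modes), -1.5, 1.5)
        base = PoseShapeParams(np.zeros(3), np.zeros(3), coeffs)
        R = Rotation.from_euler("zyx", [20, -10, 5], degrees=True)
        t = np.array([7.0, -3.0, 12.0])
        posed = PoseShapeParams(R.as_rotvec(), t, coeffs)
        for tmpl in model.path_annotations:
            p_base = propagate_path(model, base, tmpl)
            p_posed = propagate_path(model, posed, tmpl)
            assert np.allclose(p_posed.entry, R.as_matrix() @ p_base.entry + t,
                               atol=1e-9)
            assert np.allclose(p_posed.exit, R.as_matrix() @ p_base.exit + t,
                               atol=1e-9)

    def test_pure_translation(self, small_model):
        model, _ = small_model
        t = np.array([-4.0, 2.0, 9.0])
        zero = model.zero_params()
        moved = PoseShapeParams(np.zeros(3), t, np.zeros(model.n_modes))
        for tmpl in model.path_annotations:
            a = propagate_path(model, zero, tmpl)
            b = propagate_path(model, moved, tmpl)
            assert np.allclose(b.entry - a.entry, t, atol=1e-12)
            assert np.allclose(b.exit - a.exit, t, atol=1e-12)

    def test_mean_shape_path_does_not_breach(self, small_model):
        model, _ = small_model
        mesh = instantiate(model, model.zero_params())
        for tmpl in model.path_annotations:
            plan = breach_check(propagate_path(model, model.zero_params(), tmpl), mesh)
            assert plan.breach is False


class TestGeoplanTriangulate:
    def test_exact_recovery(self, two_cameras):
        entry = np.array([4.0, -18.0, 2.0])
        exit_ = np.array([1.0, 25.0, -1.0])
        uvs = []
        for p in (entry, exit_):
            uv0, _, _ = project_points(two_cameras[0], p[None])
            uv1, _, _ = project_points(two_cameras[1], p[None])
            uvs.append([uv0[0], uv1[0]])
        plan = geoplan_triangulate(uvs[0], uvs[1], two_cameras, side="right")
        assert plan.side == "right"
        assert np.linalg.norm(plan.entry - entry) < 1e-6
        assert np.linalg.norm(plan.exit - exit_) < 1e-6

    def test_missing_endpoint_raises(self, two_cameras):
        uv = np.array([60.0, 60.0])
        with pytest.raises(PlanningFailure):
            geoplan_triangulate([uv, None], [uv, uv], two_cameras)
        with pytest.raises(PlanningFailure):
            geoplan_triangulate([uv, uv], [None, uv], two_cameras)

    def test_too_few_views(self, two_cameras):
        uv = np.array([60.0, 60.0])
        with pytest.raises(ValueError):
            geoplan_triangulate([uv], [uv], two_cameras[:1])


class TestPlanSuccess:
    def test_truth_table(self):
        ok = PathPlan("left", np.zeros(3), np.array([0, 0, 20.0]))
        ok.breach = False
        breached = PathPlan("left", np.zeros(3), np.array([0, 0, 20.0]))
        breached.breach = True
        failed = PathPlan("left", np.zeros(3), np.array([0, 0, 20.0]))
        failed.breach = False
        failed.failure_reason = "entry endpoint missing in one view (left)"
        unchecked = PathPlan("left", np.zeros(3), np.array([0, 0, 20.0]))

        assert plan_success(ok, ok) is True
        assert plan_success(ok, breached) is False
        assert plan_success(breached, ok) is False
        assert plan_success(ok, None) is False
        assert plan_success(None, None) is False
        assert plan_success(ok, failed) is False
        assert plan_success(ok, unchecked) is False  # no verdict yet -> not success
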