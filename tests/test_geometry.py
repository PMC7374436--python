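"""Two-view geometry: projection, fundamental matrices, rectification and
midpoint triangulation."""

import numpy as np
import pytest

from spinetrack.exceptions import (
    BehindCameraError,
    DegenerateRigError,
    EstimationError,
    ParallelRaysError,
    RectificationError,
)
from spinetrack.geometry import (
    CameraModel,
    StereoRig,
    apply_homography,
    compute_rectification,
    estimate_fundamental,
    fundamental_from_cameras,
    load_calibration,
    normalize_fundamental,
    project,
    save_calibration,
    triangulate_midpoint,
    triangulate_rays,
)

from conftest import make_verging_rig, random_points_in_front


def identity_camera(f=1.0, pp=(0.0, 0.0)):
    return CameraModel(focal=(f, f), principal_point=pp, rotation=np.eye(3),
                       center=np.zeros(3))


class TestProject:
    def test_optical_axis(self):
        cam = identity_camera()
        assert np.allclose(project(cam, (0, 0, 1)), (0, 0))

    def test_pinhole_arithmetic(self):
        cam = identity_camera(f=100.0, pp=(50.0, 50.0))
        assert np.allclose(project(cam, (1, 2, 2)), (100, 150))

    def test_behind_camera(self):
        with pytest.raises(BehindCameraError):
            project(identity_camera(), (0, 0, -1))

    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            CameraModel(focal=(1, 1), principal_point=(0, 0),
                        rotation=np.ones((3, 3)), center=np.zeros(3))


class TestFundamental:
    def test_pure_translation_is_canonical(self):
        cam1 = identity_camera()
        cam2 = CameraModel(focal=(1, 1), principal_point=(0, 0),
                           rotation=np.eye(3), center=np.array([1.0, 0, 0]))
        F = fundamental_from_cameras(cam1, cam2)
        expected = normalize_fundamental(np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0.0]]))
        assert min(np.abs(F - expected).max(), np.abs(F + expected).max()) < 1e-12

    def test_epipolar_identity_random_points(self, verging_rig):
        rng = np.random.default_rng(0)
        for X in random_points_in_front(rng, verging_rig, 100):
            x1 = np.append(project(verging_rig.cam1, X), 1.0)
            x2 = np.append(project(verging_rig.cam2, X), 1.0)
            assert abs(x2 @ verging_rig.F @ x1) < 1e-9

    def test_identical_cameras_degenerate(self):
        cam = identity_camera()
        with pytest.raises(DegenerateRigError):
            fundamental_from_cameras(cam, cam)

    def test_rig_invariants(self, verging_rig):
        s = np.linalg.svd(verging_rig.F, compute_uv=False)
        assert s[2] < 1e-12  # rank 2
        assert np.linalg.norm(verging_rig.F @ verging_rig.e) < 1e-8
        assert np.linalg.norm(verging_rig.F.T @ verging_rig.e_prime) < 1e-8


class TestEstimateFundamental:
    def test_matches_calibrated_rig_on_noise_free_points(self, verging_rig):
        rng = np.random.default_rng(1)
        X = random_points_in_front(rng, verging_rig, 20)
        p1 = np.array([project(verging_rig.cam1, x) for x in X])
        p2 = np.array([project(verging_rig.cam2, x) for x in X])
        F = estimate_fundamental(p1, p2)
        diff = min(np.linalg.norm(F - verging_rig.F), np.linalg.norm(F + verging_rig.F))
        assert diff < 1e-6

    def test_too_few_points(self):
        pts = np.random.default_rng(0).uniform(0, 100, (7, 2))
        with pytest.raises(EstimationError):
            estimate_fundamental(pts, pts + 1)

    def test_collinear_points_degenerate(self):
        t = np.linspace(0, 1, 12)
        p1 = np.column_stack([10 * t, 20 * t])
        p2 = np.column_stack([10 * t + 5, 20 * t + 3])
        with pytest.raises(EstimationError):
            estimate_fundamental(p1, p2)


class TestRectification:
    def test_identity_on_already_rectified(self):
        F = np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0.0]])
        rng = np.random.default_rng(2)
        p1 = rng.uniform(10, 600, (30, 2))
        p2 = p1 + np.column_stack([rng.uniform(-40, -10, 30), np.zeros(30)])
        rect = compute_rectification(F, p1, p2, ((640, 480), (640, 480)))
        assert np.allclose(rect.H, np.eye(3))
        assert np.allclose(rect.H_prime, np.eye(3))
        assert rect.residual_disparity <= 1e-6

    def test_verging_rig_y_disparity_and_epipole(self, verging_rig):
        rng = np.random.default_rng(3)
        X = random_points_in_front(rng, verging_rig, 50)
        p1 = np.array([project(verging_rig.cam1, x) for x in X])
        p2 = np.array([project(verging_rig.cam2, x) for x in X])
        pre = np.mean(np.abs(p1[:, 1] - p2[:, 1]))
        rect = compute_rectification(verging_rig.F, p1, p2, ((640, 480), (640, 480)))
        assert rect.residual_disparity < 0.1
        assert rect.residual_disparity <= pre + 1e-9  # never made worse
        # epipole mapped to the point at infinity
        ep_mapped = rect.H_prime @ verging_rig.e_prime
        assert abs(ep_mapped[2]) < 1e-8 * np.linalg.norm(ep_mapped)

    def test_epipole_inside_image_rejected(self):
        # forward motion: the epipole is at the principal point
        cam1 = identity_camera(f=100.0, pp=(50.0, 50.0))
        cam2 = CameraModel(focal=(100, 100), principal_point=(50, 50),
                           rotation=np.eye(3), center=np.array([0, 0, -100.0]))
        rig = StereoRig(cam1, cam2)
        with pytest.raises(RectificationError):
            compute_rectification(rig.F, np.zeros((0, 2)), np.zeros((0, 2)),
                                  ((101, 101), (101, 101)))

    def test_rank3_matrix_rejected(self):
        with pytest.raises(RectificationError):
            compute_rectification(np.eye(3), np.zeros((0, 2)), np.zeros((0, 2)),
                                  ((10, 10), (10, 10)))


class TestTriangulation:
    def test_exact_recovery_400mm_baseline(self):
        rig = make_verging_rig(baseline=400.0, vergence_deg=0.0)
        X = np.array([10.0, 20.0, 500.0])
        t = triangulate_midpoint(rig, project(rig.cam1, X), project(rig.cam2, X))
        assert np.linalg.norm(t.point3d - X) < 1e-9
        assert t.error_mm < 1e-9

    def test_skew_ray_closed_form_example(self):
        mid, dist, p1, p2 = triangulate_rays(
            np.zeros(3), np.array([0, 0, 1.0]),
            np.array([100.0, 1.0, 0.0]), np.array([-1.0, 0, 0]),
        )
        assert dist == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(mid, (0, 0.5, 0))

    def test_parallel_rays_rejected(self):
        with pytest.raises(ParallelRaysError):
            triangulate_rays(np.zeros(3), np.array([0, 0, 1.0]),
                             np.array([1.0, 0, 0]), np.array([0, 0, 1.0]))

    def test_exact_recovery_property_random_rigs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            rig = make_verging_rig(
                baseline=rng.uniform(100, 600),
                focal=rng.uniform(500, 2000),
                vergence_deg=rng.uniform(0, 25),
            )
            for X in random_points_in_front(rng, rig, 100):
                t = triangulate_midpoint(rig, project(rig.cam1, X), project(rig.cam2, X))
                assert np.linalg.norm(t.point3d - X) < 1e-9
                assert t.error_mm < 1e-9

    def test_midpoint_error_matches_skew_line_distance(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            o1, o2 = rng.uniform(-100, 100, (2, 3))
            d1, d2 = rng.standard_normal((2, 3))
            if np.linalg.norm(np.cross(d1, d2)) < 1e-6:
                continue
            _, dist, _, _ = triangulate_rays(o1, d1, o2, d2)
            u1, u2 = d1 / np.linalg.norm(d1), d2 / np.linalg.norm(d2)
            closed = abs((o2 - o1) @ np.cross(u1, u2)) / np.linalg.norm(np.cross(u1, u2))
            assert dist == pytest.approx(closed, rel=1e-12, abs=1e-12)

    def test_result_invariants(self, verging_rig):
        t = triangulate_midpoint(verging_rig, (300, 250), (290, 251))
        p1, p2 = t.ray_points
        assert np.allclose(t.point3d, 0.5 * (p1 + p2))
        assert t.error_mm == pytest.approx(np.linalg.norm(p1 - p2))


def test_calibration_round_trip(tmp_path, verging_rig):
    path = tmp_path / "calib.json"
    save_calibration(verging_rig, path)
    rig2 = load_calibration(path)
    assert np.allclose(rig2.cam1.rotation, verging_rig.cam1.rotation)
    assert np.allclose(rig2.cam2.center, verging_rig.cam2.center)
    assert np.allclose(rig2.F, verging_rig.F)


def test_homography_export_round_trip(verging_rig):
    rng = np.random.default_rng(4)
    X = random_points_in_front(rng, verging_rig, 20)
    p1 = np.array([project(verging_rig.cam1, x) for x in X])
    p2 = np.array([project(verging_rig.cam2, x) for x in X])
    rect = compute_rectification(verging_rig.F, p1, p2, ((640, 480), (640, 480)))
    d = rect.to_dict()
    H = np.asarray(d["H"]).reshape(3, 3)
    assert np.allclose(apply_homography(H, p1), apply_homography(rect.H, p1))
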