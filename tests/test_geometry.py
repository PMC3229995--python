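"""Sphere/plane fitting, artifact filtering and cup frames."""

import numpy as np
import pytest

from cupwear import (
    CupFrame,
    FitDegeneracyError,
    PlaneFit,
    PointCloud,
    RigidTransform,
    SphereFit,
    build_cup_frame,
    filter_to_surface,
    fit_plane,
    fit_sphere,
    frame_transform,
    random_rigid_motion,
    sample_annulus_points,
    sample_sphere_points,
)

OCTAHEDRON = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
)


def algebraic_sphere_oracle(pts):
    """Independent closed-form (linearised) sphere fit used as cross-check."""
    A = np.c_[2 * pts, np.ones(len(pts))]
    b = (pts**2).sum(axis=1)
    sol = np.linalg.solve(A.T @ A, A.T @ b)
    c = sol[:3]
    return c, np.sqrt(sol[3] + c @ c)


class TestFitSphere:
    def test_exact_octahedron(self):
        fit = fit_sphere(PointCloud(OCTAHEDRON, "head"))
        assert np.allclose(fit.center, 0, atol=1e-9)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)
        assert fit.n_used == 6 and fit.n_rejected == 0

    def test_translation_equivariance(self):
        t = np.array([10.0, 20.0, 30.0])
        fit = fit_sphere(PointCloud(OCTAHEDRON + t, "head"))
        assert np.allclose(fit.center, t, atol=1e-9)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)

    def test_noisy_center_vs_algebraic_oracle(self):
        center, radius = np.array([5.0, -3.0, 12.0]), 14.0
        pts = sample_sphere_points(center, radius, 3000, sigma=0.1, seed=11)
        fit = fit_sphere(PointCloud(pts, "head"))
        assert np.abs(fit.center - center).max() < 0.02
        # the geometric fit must agree with the independent algebraic fit
        c_alg, r_alg = algebraic_sphere_oracle(pts)
        assert np.abs(fit.center - c_alg).max() < 0.01
        assert fit.radius == pytest.approx(r_alg, abs=0.01)

    def test_center_bias_on_hemispherical_coverage(self):
        """Center estimate is unbiased (< 0.02 mm per axis) at sigma = 0.1 mm."""
        center, radius = np.zeros(3), 14.0
        centers = []
        for seed in range(50):
            pts = sample_sphere_points(
                center, radius, 3000, cap_direction=(0, 0, -1), cap_angle=90.0,
                sigma=0.1, seed=seed,
            )
            centers.append(fit_sphere(PointCloud(pts, "cup_outer")).center)
        bias = np.mean(centers, axis=0) - center
        assert np.abs(bias).max() < 0.02

    def test_rigid_motion_invariance_of_recovery(self):
        pts = sample_sphere_points([1.0, 2.0, 3.0], 10.0, 500, sigma=0.0, seed=3)
        motion = random_rigid_motion(50, 30, seed=9)
        fit = fit_sphere(PointCloud(motion.apply(pts), "head"))
        expected_center = motion.apply(np.array([[1.0, 2.0, 3.0]]))[0]
        assert np.abs(fit.center - expected_center).max() < 1e-9
        assert fit.radius == pytest.approx(10.0, abs=1e-9)

    def test_outliers_rejected_and_conserved(self):
        pts = sample_sphere_points(np.zeros(3), 10.0, 400, sigma=0.0, seed=1)
        dirs = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts[:20] += 1.5 * dirs[:20]  # artifacts well past the threshold
        fit = fit_sphere(PointCloud(pts, "head"), filter_threshold=0.5)
        assert fit.n_rejected == 20
        assert fit.n_used + fit.n_rejected == 400
        assert fit.radius == pytest.approx(10.0, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(FitDegeneracyError):
            fit_sphere(PointCloud(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]]), "head"))
        coplanar = np.c_[np.random.default_rng(0).normal(size=(50, 2)), np.zeros(50)]
        with pytest.raises(FitDegeneracyError):
            fit_sphere(PointCloud(coplanar, "head"))


class TestFitPlane:
    def test_exact_unit_square(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        fit = fit_plane(PointCloud(pts, "plane1"))
        assert np.allclose(np.abs(fit.normal), [0, 0, 1], atol=1e-9)
        assert fit.offset == pytest.approx(0.0, abs=1e-9)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_exact_oblique_plane(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(-5, 5, size=(200, 2))
        pts = np.c_[xy, 3.0 - xy.sum(axis=1)]  # x + y + z = 3
        fit = fit_plane(PointCloud(pts, "plane1"))
        n_expected = np.ones(3) / np.sqrt(3)
        sign = np.sign(fit.normal @ n_expected)
        assert np.allclose(sign * fit.normal, n_expected, atol=1e-9)
        assert sign * fit.offset == pytest.approx(np.sqrt(3), abs=1e-9)

    def test_orientation_follows_reference_point(self):
        pts = np.array([[0, 0, 2], [1, 0, 2], [0, 1, 2], [1, 1, 2]], float)
        up = fit_plane(PointCloud(pts, "plane1"), positive_side=[0, 0, 10])
        down = fit_plane(PointCloud(pts, "plane1"), positive_side=[0, 0, -10])
        assert np.allclose(up.normal, [0, 0, 1], atol=1e-9)
        assert np.allclose(down.normal, [0, 0, -1], atol=1e-9)
        assert up.offset == pytest.approx(2.0, abs=1e-9)
        assert down.offset == pytest.approx(-2.0, abs=1e-9)

    def test_outliers_rejected_vs_inlier_only_tls_oracle(self):
        rng = np.random.default_rng(21)
        inliers = np.c_[
            rng.uniform(-10, 10, size=(500, 2)), 2.0 + rng.normal(0, 0.15, 500)
        ]
        outliers = np.c_[
            rng.uniform(-10, 10, size=(50, 2)),
            2.0 + (1.0 + rng.uniform(0, 1, 50)) * rng.choice([-1, 1], 50),
        ]
        pts = np.vstack([inliers, outliers])
        fit = fit_plane(PointCloud(pts, "plane1"), filter_threshold=0.5,
                        positive_side=[0, 0, 100])
        assert fit.n_rejected == 50
        assert abs(fit.offset - 2.0) < 0.02
        # oracle: closed-form TLS on the 500 inliers only
        centroid = inliers.mean(axis=0)
        _, _, vt = np.linalg.svd(inliers - centroid)
        n = vt[-1] * np.sign(vt[-1][2])
        assert np.abs(fit.normal - n).max() < 1e-3
        assert fit.offset == pytest.approx(n @ centroid, abs=1e-3)

    def test_collinear_points_degenerate(self):
        pts = np.outer(np.linspace(0, 1, 30), [1.0, 2.0, 3.0])
        with pytest.raises(FitDegeneracyError):
            fit_plane(PointCloud(pts, "plane1"))


class TestFilterToSurface:
    def residual_from(self, values):
        values = np.asarray(values, float)
        return lambda pts: values

    def test_no_op_when_all_within(self):
        cloud = PointCloud(np.arange(12.0).reshape(4, 3), "head")
        kept, rejected = filter_to_surface(
            cloud, self.residual_from([0.1, 0.5, 0.3, 0.0]), 0.5
        )
        assert len(kept) == 4 and len(rejected) == 0

    def test_strict_exceedance_rule(self):
        """Residual exactly at the threshold is retained ('more than' rule)."""
        cloud = PointCloud(np.arange(9.0).reshape(3, 3), "head")
        kept, rejected = filter_to_surface(
            cloud, self.residual_from([0.5, 0.6, 0.2]), 0.5
        )
        assert len(kept) == 2 and len(rejected) == 1
        assert np.allclose(rejected.points[0], cloud.points[1])

    def test_partition_preserves_order_and_count(self, rng):
        pts = rng.normal(size=(200, 3))
        res = rng.uniform(0, 1, 200)
        cloud = PointCloud(pts, "head")
        kept, rejected = filter_to_surface(cloud, lambda p: res, 0.5)
        assert len(kept) + len(rejected) == 200
        assert np.array_equal(kept.points, pts[res <= 0.5])
        assert np.array_equal(rejected.points, pts[res > 0.5])


def _frame_from_synthetic(tilt=5.0, origin=(0.0, 0.0, 0.0), motion=None, seed=0):
    """Cup sphere + two tilted opening faces, optionally rigidly moved."""
    origin = np.asarray(origin, float)
    sphere_pts = sample_sphere_points(
        origin, 27.0, 800, cap_direction=(0, 0, -1), cap_angle=90, seed=seed
    )
    p1 = sample_annulus_points(origin + [0, 0, 0.0],
                               [0, np.sin(np.deg2rad(-tilt)), np.cos(np.deg2rad(tilt))],
                               16, 25, 300, seed=seed + 1)
    p2 = sample_annulus_points(origin + [0, 0, 2.0],
                               [0, np.sin(np.deg2rad(tilt)), np.cos(np.deg2rad(tilt))],
                               16, 25, 300, seed=seed + 2)
    ref = origin + np.array([0.0, 0.0, 10.0])
    if motion is not None:
        sphere_pts, p1, p2 = map(motion.apply, (sphere_pts, p1, p2))
        ref = motion.apply(ref[None, :])[0]
    sphere = fit_sphere(PointCloud(sphere_pts, "cup_outer"))
    f1 = fit_plane(PointCloud(p1, "plane1"), positive_side=ref)
    f2 = fit_plane(PointCloud(p2, "plane2"), positive_side=ref)
    return build_cup_frame(sphere, f1, f2)


class TestCupFrame:
    def test_orthonormal_right_handed_and_oriented(self):
        frame = _frame_from_synthetic(tilt=5.0)
        R = frame.rotation
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        # z away from the dome (dome points toward -z here)
        assert np.degrees(np.arccos(frame.z_axis @ [0, 0, 1])) < 5.0
        assert np.abs(frame.origin).max() < 1e-6

    def test_rotation_equivariance(self):
        base = _frame_from_synthetic(tilt=5.0)
        for seed in range(5):
            motion = random_rigid_motion(50, 30, seed=seed)
            moved = _frame_from_synthetic(tilt=5.0, motion=motion)
            assert np.abs(moved.origin - motion.apply(base.origin[None])[0]).max() < 1e-6
            for axis in ("x_axis", "y_axis", "z_axis"):
                expected = motion.rotation @ getattr(base, axis)
                assert np.abs(getattr(moved, axis) - expected).max() < 1e-6

    def test_translation_invariance_of_axes(self):
        base = _frame_from_synthetic(tilt=5.0)
        t = np.array([12.0, -7.0, 30.0])
        moved = _frame_from_synthetic(tilt=5.0, origin=t)
        assert np.abs(moved.origin - t).max() < 1e-6
        for axis in ("x_axis", "y_axis", "z_axis"):
            assert np.abs(getattr(moved, axis) - getattr(base, axis)).max() < 1e-9

    def test_invalid_frames_rejected(self):
        with pytest.raises(ValueError):
            CupFrame(np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, 0, 0]),
                     np.array([0.0, 0, 1]))
        with pytest.raises(ValueError):  # left-handed
            CupFrame(np.zeros(3), np.array([1.0, 0, 0]), np.array([0.0, 1, 0]),
                     np.array([0.0, 0, -1]))


def _axes_frame(origin, Rdeg_z=0.0):
    c, s = np.cos(np.deg2rad(Rdeg_z)), np.sin(np.deg2rad(Rdeg_z))
    return CupFrame(np.asarray(origin, float),
                    np.array([c, s, 0.0]), np.array([-s, c, 0.0]),
                    np.array([0.0, 0.0, 1.0]))


class TestFrameTransform:
    def test_identity(self):
        f = _axes_frame([1.0, 2.0, 3.0], 30.0)
        T = frame_transform(f, f)
        assert np.abs(T.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(T.translation).max() < 1e-9

    def test_quarter_turn_is_permutation(self):
        a = _axes_frame([0, 0, 0], 0.0)
        b = _axes_frame([0, 0, 0], 90.0)
        T = frame_transform(a, b)
        expected = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        assert np.abs(T.rotation - expected).max() < 1e-9

    def test_round_trip_on_random_points(self, rng):
        fa = _frame_from_synthetic(tilt=4.0, seed=10)
        fb = _frame_from_synthetic(tilt=6.0, origin=(5, -2, 8), seed=20)
        T = frame_transform(fa, fb)
        pts = rng.normal(scale=30, size=(100, 3))
        # frame-relative coordinates are preserved
        assert np.abs(fb.to_local(T.apply(pts)) - fa.to_local(pts)).max() < 1e-9
        back = frame_transform(fb, fa)
        assert np.abs(back.apply(T.apply(pts)) - pts).max() < 1e-9


class TestRigidTransform:
    def test_compose_inverse_identity(self, rng):
        m = random_rigid_motion(50, 30, seed=5)
        pts = rng.normal(size=(50, 3))
        assert np.abs(m.inverse().apply(m.apply(pts)) - pts).max() < 1e-9

    def test_improper_rotation_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))


def test_fit_conservation_invariant(noisy_pair):
    """n_used + n_rejected equals the input size for every fitted surface."""
    pre, post, _ = noisy_pair
    for scan in (pre, post):
        for label in ("cup_outer", "head", "cup_inner"):
            cloud = getattr(scan, label)
            fit = fit_sphere(cloud)
            assert fit.n_used + fit.n_rejected == len(cloud)
        for label in ("plane1", "plane2"):
            cloud = getattr(scan, label)
            fit = fit_plane(cloud)
            assert fit.n_used + fit.n_rejected == len(cloud)


def test_point_cloud_validation():
    with pytest.raises(ValueError):
        PointCloud(np.array([[0.0, 0.0, np.nan]]), "head")
    with pytest.raises(ValueError):
        PointCloud(np.zeros((1, 3)), "hat")
    with pytest.raises(ValueError):
        PointCloud(np.zeros((0, 3)), "head")
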