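import math

import numpy as np
import pytest
from scipy.optimize import minimize

from conftest import surface_cloud
from jawtrack.exceptions import DegenerateGeometryError, EmptyMaskError
from jawtrack.extraction import PointCloud
from jawtrack.geometry2d import RigidTransform2D, ScaledTransform2D, rotation_matrix
from jawtrack.registration import (
    Pairing,
    RegistrationConfig,
    error_series,
    extract_observed_cloud,
    fit_rigid_point_to_plane,
    fit_scaling,
    lifted_apply,
    pair_points,
    register_frame,
    rough_transform,
    superimposition_error,
    track_sequence,
)


def _identity_pairing(n):
    return Pairing(indices=np.arange(n), offsets=np.zeros((n, 3)), distances=np.zeros(n))


def _moved_copy(cloud, transform):
    xyz = lifted_apply(transform, cloud.xyz)
    return PointCloud(
        xyz=xyz,
        rows=cloud.rows.copy(),
        cols=cloud.cols.copy(),
        slice_ids=cloud.slice_ids.copy(),
        normals=None,
        weights=None,
    )


def _objective(model, observed, pairing, theta, t, h=(1.0, 1.0), weights=None):
    """Independent evaluation of the weighted point-to-plane objective."""
    x = model.xyz[:, :2] * np.asarray(h)
    p = x @ rotation_matrix(theta).T + np.asarray(t)
    lifted = np.column_stack([p, model.xyz[:, 2]])
    q = observed.xyz[pairing.indices]
    r = np.einsum("ij,ij->i", model.normals, lifted - q)
    w = np.ones(len(model)) if weights is None else weights
    return float(np.sum(w * r * r))


class TestPairPoints:
    def test_self_pairing(self):
        cloud = surface_cloud(6, 6)
        pairing = pair_points(cloud.xyz, cloud)
        np.testing.assert_array_equal(pairing.indices, np.arange(len(cloud)))
        np.testing.assert_allclose(pairing.distances, 0.0, atol=1e-12)

    def test_simple_nearest(self):
        obs = PointCloud(
            xyz=np.array([[1.0, 0, 0], [3.0, 0, 0]]),
            rows=np.zeros(2, dtype=int),
            cols=np.arange(2),
            slice_ids=np.ones(2, dtype=int),
        )
        pairing = pair_points(np.array([[0.0, 0.0, 0.0]]), obs)
        assert pairing.indices[0] == 0
        assert pairing.distances[0] == pytest.approx(1.0)

    def test_empty_observed(self):
        empty = PointCloud(
            xyz=np.zeros((0, 3)), rows=np.zeros(0, dtype=int), cols=np.zeros(0, dtype=int), slice_ids=np.zeros(0, dtype=int)
        )
        with pytest.raises(EmptyMaskError):
            pair_points(np.zeros((1, 3)), empty)

    def test_against_bruteforce(self, rng):
        model = rng.uniform(0, 10, (200, 3))
        obs_xyz = rng.uniform(0, 10, (300, 3))
        obs = PointCloud(
            xyz=obs_xyz,
            rows=np.zeros(300, dtype=int),
            cols=np.arange(300),
            slice_ids=np.ones(300, dtype=int),
        )
        pairing = pair_points(model, obs)
        d2 = np.linalg.norm(model[:, None, :] - obs_xyz[None, :, :], axis=2)
        np.testing.assert_array_equal(pairing.indices, np.argmin(d2, axis=1))
        np.testing.assert_allclose(pairing.distances, d2.min(axis=1), atol=1e-12)


class TestSuperimpositionError:
    def test_coincident_clouds(self):
        cloud = surface_cloud(6, 6)
        pairing = pair_points(cloud.xyz, cloud)
        assert superimposition_error(cloud.xyz, cloud.normals, cloud, pairing) == 0.0

    def test_projection_picks_component(self):
        obs = PointCloud(
            xyz=np.zeros((1, 3)), rows=np.zeros(1, dtype=int), cols=np.zeros(1, dtype=int), slice_ids=np.ones(1, dtype=int)
        )
        pts = np.array([[2.0, 5.0, 0.0]])
        normals = np.array([[1.0, 0.0, 0.0]])
        assert superimposition_error(pts, normals, obs, _identity_pairing(1)) == pytest.approx(2.0)

    def test_mean_of_two(self):
        obs = PointCloud(
            xyz=np.zeros((2, 3)), rows=np.zeros(2, dtype=int), cols=np.arange(2), slice_ids=np.ones(2, dtype=int)
        )
        pts = np.array([[1.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        normals = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert superimposition_error(pts, normals, obs, _identity_pairing(2)) == pytest.approx(2.0)

    def test_per_pair_recomputation_oracle(self, rng):
        cloud = surface_cloud(8, 8)
        obs = _moved_copy(cloud, RigidTransform2D(0.02, 0.3, -0.2))
        pairing = pair_points(cloud.xyz, obs)
        err = superimposition_error(cloud.xyz, cloud.normals, obs, pairing)
        acc = [
            abs(float(cloud.normals[i] @ (cloud.xyz[i] - obs.xyz[pairing.indices[i]])))
            for i in range(len(cloud))
        ]
        assert err == pytest.approx(float(np.mean(acc)), abs=1e-12)


class TestFitRigidPointToPlane:
    def test_zero_on_identical(self):
        cloud = surface_cloud(8, 8)
        fit = fit_rigid_point_to_plane(_identity_pairing(len(cloud)), cloud, cloud)
        assert abs(fit.theta) < 1e-9 and abs(fit.tx) < 1e-9 and abs(fit.ty) < 1e-9

    def test_translation_recovery(self):
        cloud = surface_cloud(10, 10)
        obs = _moved_copy(cloud, RigidTransform2D(0.0, 1.0, 0.0))
        fit = fit_rigid_point_to_plane(_identity_pairing(len(cloud)), cloud, obs)
        assert abs(fit.tx - 1.0) < 1e-6 and abs(fit.ty) < 1e-6 and abs(fit.theta) < 1e-6

    def test_rotation_recovery_and_grid_oracle(self):
        cloud = surface_cloud(10, 10)
        centroid = cloud.xyz[:, :2].mean(axis=0)
        truth = math.radians(2.0)
        r = rotation_matrix(truth)
        t_true = centroid - r @ centroid
        obs = _moved_copy(cloud, RigidTransform2D(truth, t_true[0], t_true[1]))
        pairing = _identity_pairing(len(cloud))
        fit = fit_rigid_point_to_plane(pairing, cloud, obs)
        assert math.degrees(abs(fit.theta - truth)) < 0.05

        obj_fit = _objective(cloud, obs, pairing, fit.theta, (fit.tx, fit.ty))
        # coarse grid over (theta, tx, ty) must not beat the fit
        best = np.inf
        for th in np.radians(np.linspace(1.0, 3.0, 21)):
            for tx in np.linspace(t_true[0] - 0.2, t_true[0] + 0.2, 9):
                for ty in np.linspace(t_true[1] - 0.2, t_true[1] + 0.2, 9):
                    best = min(best, _objective(cloud, obs, pairing, th, (tx, ty)))
        assert obj_fit <= best + 1e-9

    def test_degenerate_parallel_normals(self):
        n = 12
        cloud = PointCloud(
            xyz=np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)]),
            rows=np.zeros(n, dtype=int),
            cols=np.arange(n),
            slice_ids=np.ones(n, dtype=int),
            normals=np.tile([0.0, 0.0, 1.0], (n, 1)),
        )
        with pytest.raises(DegenerateGeometryError):
            fit_rigid_point_to_plane(_identity_pairing(n), cloud, cloud)


class TestFitScaling:
    def test_identity(self):
        cloud = surface_cloud(10, 10)
        fit = fit_scaling(_identity_pairing(len(cloud)), cloud, cloud, theta=0.0)
        assert fit.h11 == pytest.approx(1.0, abs=1e-9)
        assert fit.h22 == pytest.approx(1.0, abs=1e-9)
        assert abs(fit.tx) < 1e-9 and abs(fit.ty) < 1e-9

    def test_x_stretch_and_numeric_minimizer_oracle(self):
        cloud = surface_cloud(10, 10)
        obs = _moved_copy(cloud, ScaledTransform2D(0.0, 0.0, 0.0, 1.1, 1.0))
        pairing = _identity_pairing(len(cloud))
        fit = fit_scaling(pairing, cloud, obs, theta=0.0)
        assert fit.h11 == pytest.approx(1.1, abs=1e-3)
        assert fit.h22 == pytest.approx(1.0, abs=1e-3)

        def f(p):
            return _objective(cloud, obs, pairing, 0.0, p[2:], h=(p[0], p[1]))

        oracle = minimize(f, [1.0, 1.0, 0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
        assert f([fit.h11, fit.h22, fit.tx, fit.ty]) <= oracle.fun + 1e-9

    def test_clamping_at_bounds(self):
        cloud = surface_cloud(10, 10)
        obs = _moved_copy(cloud, ScaledTransform2D(0.0, 0.0, 0.0, 1.5, 1.0))
        fit = fit_scaling(_identity_pairing(len(cloud)), cloud, obs, theta=0.0)
        assert fit.h11 == pytest.approx(1.25)


class TestRegisterFrame:
    def test_identity_case(self):
        cloud = surface_cloud(10, 10)
        reg = register_frame(cloud, cloud, RigidTransform2D.identity())
        assert reg.converged
        assert reg.n_iterations == 1
        assert reg.superimposition_error == pytest.approx(0.0, abs=1e-12)
        t = reg.transform
        assert abs(t.theta) < 1e-9 and abs(t.tx) < 1e-9 and abs(t.ty) < 1e-9

    def test_translation_recovery_with_offset_init(self):
        cloud = surface_cloud(12, 12)
        truth = RigidTransform2D(0.0, 2.0, -1.5)
        obs = _moved_copy(cloud, truth)
        reg = register_frame(cloud, obs, RigidTransform2D(0.0, 2.5, -1.5))
        assert abs(reg.transform.tx - 2.0) < 0.1 and abs(reg.transform.ty + 1.5) < 0.1

    def test_rotation_recovery_from_rough_landmarks(self):
        cloud = surface_cloud(12, 12)
        truth = RigidTransform2D(math.radians(15.0), 3.0, 1.0)
        obs = _moved_copy(cloud, truth)
        lms = np.array([[2.0, 2.0], [8.0, 3.0], [5.0, 9.0]])
        from jawtrack.geometry2d import fit_rigid_svd

        rough = fit_rigid_svd(lms, truth.apply(lms))
        reg = register_frame(cloud, obs, rough)
        assert math.degrees(abs(reg.transform.theta - truth.theta)) < 0.5
        t_est = reg.transform.apply(cloud.xyz[:1, :2])
        t_true = truth.apply(cloud.xyz[:1, :2])
        assert np.linalg.norm(t_est - t_true) < 0.25

    def test_error_not_above_init_error(self):
        cloud = surface_cloud(12, 12)
        obs = _moved_copy(cloud, RigidTransform2D(0.01, 0.4, -0.2))
        init = RigidTransform2D.identity()
        p = lifted_apply(ScaledTransform2D.from_rigid(init), cloud.xyz)
        e0 = superimposition_error(p, cloud.normals, obs, pair_points(p, obs))
        reg = register_frame(cloud, obs, init)
        assert reg.superimposition_error <= e0 + 1e-12

    def test_identity_robust_to_small_init_perturbations(self):
        cloud = surface_cloud(12, 12)
        for dtheta, dx, dy in [(0.5, 0.3, 0.0), (-0.8, 0.0, 0.5), (1.0, 1.0, -1.0)]:
            init = RigidTransform2D(math.radians(dtheta), dx, dy)
            reg = register_frame(cloud, cloud, init)
            assert abs(math.degrees(reg.transform.theta)) < 0.1
            assert abs(reg.transform.tx) < 0.1 and abs(reg.transform.ty) < 0.1

    def test_random_rigid_motions_compose_to_identity(self, rng):
        cloud = surface_cloud(12, 12)
        for _ in range(20):
            truth = RigidTransform2D(
                math.radians(rng.uniform(-20, 20)), rng.uniform(-5, 5), rng.uniform(-5, 5)
            )
            obs = _moved_copy(cloud, truth)
            reg = register_frame(cloud, obs, truth)  # exact init; fit must stay
            combined = reg.transform.rigid_part().compose(truth.inverse())
            assert abs(math.degrees(combined.theta)) < 0.2
            assert np.hypot(combined.tx, combined.ty) < 0.2

    def test_weight_scale_invariance(self):
        cloud = surface_cloud(10, 10)
        cloud.weights = np.ones(len(cloud))
        obs = _moved_copy(cloud, RigidTransform2D(0.005, 0.2, 0.1))
        reg1 = register_frame(cloud, obs, RigidTransform2D.identity())
        doubled = cloud.subset(np.ones(len(cloud), dtype=bool))
        doubled.weights = 2.0 * cloud.weights
        reg2 = register_frame(doubled, obs, RigidTransform2D.identity())
        assert reg1.transform.theta == pytest.approx(reg2.transform.theta, abs=1e-12)
        assert reg1.transform.tx == pytest.approx(reg2.transform.tx, abs=1e-12)
        assert reg1.transform.h11 == pytest.approx(reg2.transform.h11, abs=1e-12)


class TestTrackSequence:
    def test_static_sequence(self):
        from jawtrack.synthetic import PhantomSpec, generate_phantom

        spec = PhantomSpec(n_frames=5, n_slices=2, max_translation_mm=0.0, max_rotation_deg=0.0)
        frames, truth = generate_phantom(spec)
        res = track_sequence(frames, truth.annotation)
        for reg in res.frames:
            assert reg.converged
            assert abs(math.degrees(reg.transform.theta)) < 0.05
            assert np.hypot(reg.transform.tx, reg.transform.ty) < 0.05
            assert reg.superimposition_error < 1e-6

    def test_phantom_recovery(self, small_phantom, small_tracking):
        frames, truth = small_phantom
        res = small_tracking
        c1 = truth.condyle_center
        terr = [
            np.linalg.norm(r.transform.apply(c1[None, :]) - t.apply(c1[None, :]))
            for r, t in zip(res.frames, truth.transforms)
        ]
        rerr = [
            abs(math.degrees(r.transform.theta - t.theta))
            for r, t in zip(res.frames, truth.transforms)
        ]
        px = frames.pixel_spacing[0]
        assert np.sqrt(np.mean(np.square(terr))) <= 0.5 * px
        assert np.sqrt(np.mean(np.square(rerr))) <= 0.5

    def test_tracked_beats_rough_mask_only(self, small_phantom, small_tracking):
        frames, truth = small_phantom
        res = small_tracking
        cfg = RegistrationConfig()
        roughs = [rough_transform(truth.annotation, f) for f in range(1, frames.n_frames + 1)]
        observed = [
            extract_observed_cloud(frames, truth.annotation, f, roughs[f - 1], res.params, cfg)
            for f in range(1, frames.n_frames + 1)
        ]
        rough_errors = error_series([ScaledTransform2D.from_rigid(r) for r in roughs], res.model, observed)
        tracked = res.errors
        # frame 1 is exact for both; compare the moving frames
        better = tracked[1:] <= rough_errors[1:] + 1e-12
        assert better.mean() >= 0.95

    def test_frame1_is_identity(self, small_tracking):
        t = small_tracking.frames[0].transform
        assert abs(t.theta) < 1e-6 and np.hypot(t.tx, t.ty) < 1e-3
        assert small_tracking.frames[0].superimposition_error < 1e-6
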