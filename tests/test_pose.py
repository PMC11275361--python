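"""Pose estimation: augmentation, P3P/RANSAC/LM, direct vs concatenation."""

import numpy as np
import pytest

from probetrack import (
    ObservationFrame,
    RigidTransform,
    augment,
    estimate_pose,
    pose_concat,
    pose_direct,
    project,
)
from probetrack.errors import DegenerateConfiguration
from probetrack.pose import CorrespondenceSet, build_correspondences, solve_p3p
from probetrack.synthetic import SimConfig, simulate_observations, simulate_trajectory


def _corr_from_markers(centers3d):
    """Correspondence set with one dummy corner quartet per marker centre."""
    p3, p2, tags, mids = [], [], [], []
    for k, c in enumerate(centers3d):
        quad = np.asarray(c) + np.array(
            [[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0]], float)
        p3.append(quad)
        p2.append(quad[:, :2])
        tags += ["corner"] * 4
        mids += [k] * 4
    return CorrespondenceSet(np.concatenate(p3), np.concatenate(p2),
                             np.array(tags, dtype=object), np.array(mids))


class TestAugment:
    @pytest.mark.parametrize("k,expected", [(1, 0), (2, 1), (3, 3), (4, 6)])
    def test_pair_count(self, k, expected):
        corr = _corr_from_markers([[10.0 * i, 0.0, 0.0] for i in range(k)])
        out = augment(corr)
        assert int(np.sum(out.origin_tags == "augmented")) == expected
        assert len(out) == 4 * k + expected

    def test_midpoint_of_centres(self):
        corr = _corr_from_markers([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        out = augment(corr)
        aug3 = out.points3d[out.origin_tags == "augmented"]
        assert np.allclose(aug3, [[5.0, 0.0, 0.0]])

    def test_originals_unchanged(self):
        corr = _corr_from_markers([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        out = augment(corr)
        assert np.array_equal(out.points3d[:8], corr.points3d)
        assert np.array_equal(out.points2d[:8], corr.points2d)


class TestP3P:
    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_truth_among_candidates(self, seed, rng):
        r = np.random.default_rng(seed)
        T = RigidTransform.random(r, t_scale=30.0)
        T = RigidTransform(T.R, T.t + [0.0, 0.0, 500.0])
        obj = r.normal(size=(3, 3)) * 40.0
        cam_pts = T.apply(obj)
        bearings = cam_pts / np.linalg.norm(cam_pts, axis=1, keepdims=True)
        sols = solve_p3p(obj, bearings)
        assert sols
        best = min(np.linalg.norm(s.t - T.t) for s in sols)
        assert best < 1e-6


def _frame_and_truth(cfg, idx=0):
    truth = simulate_trajectory(cfg)
    frames = simulate_observations(truth, cfg)
    frame = frames[idx]
    return frame, truth(frame.timestamp)


class TestEstimatePose:
    def test_noiseless_recovery(self, model, camera):
        cfg = SimConfig(duration=0.2, seed=5)
        frame, T_true = _frame_and_truth(cfg)
        assert len(frame.detections) >= 2
        lut = {f.marker_id: f.corners_local for f in model.faces}
        est = estimate_pose(augment(build_correspondences(frame, lut)), camera)
        assert np.linalg.norm(est.T.t - T_true.t) < 1e-3
        assert est.T.rotation_angle_to(T_true) < 1e-5
        assert est.inlier_mask.all()

    def test_too_few_points(self, camera):
        corr = CorrespondenceSet(np.zeros((3, 3)), np.zeros((3, 2)),
                                 np.array(["corner"] * 3, dtype=object),
                                 np.zeros(3, dtype=int))
        with pytest.raises(DegenerateConfiguration):
            estimate_pose(corr, camera)

    def test_collinear_points(self, camera):
        p3 = np.stack([np.arange(6.0), np.zeros(6), np.zeros(6)], axis=-1)
        corr = CorrespondenceSet(p3, np.zeros((6, 2)),
                                 np.array(["corner"] * 6, dtype=object),
                                 np.zeros(6, dtype=int))
        with pytest.raises(DegenerateConfiguration):
            estimate_pose(corr, camera)

    def test_gross_outliers_rejected(self, model, camera):
        cfg = SimConfig(duration=0.2, seed=6)
        frame, T_true = _frame_and_truth(cfg)
        lut = {f.marker_id: f.corners_local for f in model.faces}
        corr = augment(build_correspondences(frame, lut))
        rng = np.random.default_rng(99)
        n_out = max(1, len(corr) // 5)           # 20% gross 2D outliers
        bad = rng.choice(len(corr), size=n_out, replace=False)
        p2 = corr.points2d.copy()
        p2[bad] += rng.uniform(60.0, 200.0, size=(n_out, 2))
        corr = CorrespondenceSet(corr.points3d, p2, corr.origin_tags,
                                 corr.marker_ids)
        est = estimate_pose(corr, camera, {"seed": 3})
        assert not est.inlier_mask[bad].any()
        assert np.linalg.norm(est.T.t - T_true.t) < 1e-3

    def test_deterministic(self, model, camera):
        cfg = SimConfig(duration=0.2, seed=7, pixel_noise_px=0.5)
        frame, _ = _frame_and_truth(cfg)
        lut = {f.marker_id: f.corners_local for f in model.faces}
        corr = augment(build_correspondences(frame, lut))
        a = estimate_pose(corr, camera, {"seed": 11})
        b = estimate_pose(corr, camera, {"seed": 11})
        assert a.T.is_close(b.T, atol=0.0) or a.T.is_close(b.T, atol=1e-15)
        assert np.array_equal(a.inlier_mask, b.inlier_mask)
        assert a.rms_reproj_px == b.rms_reproj_px

    def test_refinement_never_worse_than_init(self, model, camera):
        cfg = SimConfig(duration=0.3, seed=8, pixel_noise_px=1.0)
        truth = simulate_trajectory(cfg)
        lut = {f.marker_id: f.corners_local for f in model.faces}
        for frame in simulate_observations(truth, cfg)[:5]:
            corr = augment(build_correspondences(frame, lut))
            est = estimate_pose(corr, camera, {"seed": 1})
            assert est.rms_reproj_px <= est.rms_initial_px + 1e-12


class TestDirectVsConcat:
    def test_identity_probe_matrices_agree(self, model, camera):
        cfg = SimConfig(duration=0.2, seed=9)
        frame, _ = _frame_and_truth(cfg)
        I = RigidTransform.identity()
        est_d = pose_direct(frame, model, I, camera, {"seed": 2})
        est_c, T_cp = pose_concat(frame, model, I, camera, {"seed": 2})
        assert est_d.T.is_close(est_c.T, atol=1e-6)
        assert T_cp.is_close(est_c.T, atol=1e-12)

    def test_noiseless_equivalence_and_truth(self, model, camera):
        cfg = SimConfig(duration=0.2, seed=10)
        frame, T_true = _frame_and_truth(cfg)
        T_probe = cfg.T_probe_true
        est_d = pose_direct(frame, model, T_probe, camera, {"seed": 2})
        _, T_cp = pose_concat(frame, model, T_probe, camera, {"seed": 2})
        T_expected = T_true.compose(T_probe)
        assert np.linalg.norm(est_d.T.t - T_expected.t) < 1e-3
        assert np.linalg.norm(est_d.T.t - T_cp.t) < 1e-6
        assert est_d.T.rotation_angle_to(T_cp) < 1e-8

    def test_empty_frame(self, model, camera):
        frame = ObservationFrame(timestamp=0.0, detections=())
        with pytest.raises(DegenerateConfiguration):
            pose_direct(frame, model, RigidTransform.identity(), camera)

    def test_single_marker_recovery(self, model, camera):
        # one visible marker: 4 coplanar corners, planar PnP with ambiguity guard
        T_true = RigidTransform(np.eye(3), [0.0, 0.0, 400.0])
        mid = sorted(
            __import__("probetrack").visible_markers(camera, T_true, model))[0]
        px = project(camera, T_true, model.face_by_id(mid).corners_local)
        frame = ObservationFrame(timestamp=0.0, detections=((mid, px),))
        est, _ = pose_concat(frame, model, RigidTransform.identity(), camera,
                             {"seed": 4})
        assert np.linalg.norm(est.T.t - T_true.t) < 1e-3

    def test_camera_equivariance(self, model, camera):
        # moving the camera frame by G transforms every estimate T to G @ T
        cfg = SimConfig(duration=0.2, seed=12)
        frame, _ = _frame_and_truth(cfg)
        lut = {f.marker_id: f.corners_local for f in model.faces}
        est = estimate_pose(augment(build_correspondences(frame, lut)), camera,
                            {"seed": 5})
        G = RigidTransform.from_rotvec_trans([0.02, -0.01, 0.03], [5.0, -3.0, 10.0])
        moved = []
        for mid, _ in frame.detections:
            pts = model.face_by_id(mid).corners_local
            moved.append((mid, project(
                camera, G.compose(est.T), pts)))
        frame_g = ObservationFrame(timestamp=0.0, detections=tuple(moved))
        est_g = estimate_pose(
            augment(build_correspondences(frame_g, lut)), camera, {"seed": 5})
        assert est_g.T.is_close(G.compose(est.T), atol=1e-6)
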