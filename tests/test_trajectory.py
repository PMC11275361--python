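"""Trajectory filtering, resampling, registration, corner mapping, stats."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation, Slerp

from probetrack import (
    PoseStream,
    RigidTransform,
    USImageSpec,
    error_stats,
    image_corners,
    kabsch_umeyama,
    map_corners,
    map_image_pixels,
    reference_chain,
    resample,
    savgol_translations,
)
from probetrack.errors import (
    DegenerateConfiguration,
    OutOfRange,
    ShapeMismatch,
    WindowTooLarge,
)


def _rz(deg):
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def _stream(ts, translations, rotations=None):
    n = len(ts)
    rotations = rotations if rotations is not None else [np.eye(3)] * n
    poses = tuple(RigidTransform(R, t) for R, t in zip(rotations, translations))
    return PoseStream(np.asarray(ts, float), poses)


class TestSavgol:
    def test_constant_stream_unchanged(self):
        ts = np.arange(30) / 60.0
        s = _stream(ts, [[1.0, 2.0, 3.0]] * 30)
        out = savgol_translations(s, 15, 3)
        assert np.allclose(out.translations(), s.translations(), atol=1e-12)

    def test_cubic_polynomial_reproduced(self):
        ts = np.arange(40) / 60.0
        tr = np.stack([2.0 + 3.0 * ts - ts**2 + 0.5 * ts**3,
                       -1.0 + ts**2,
                       ts**3], axis=-1)
        out = savgol_translations(_stream(ts, tr), 15, 3)
        assert np.allclose(out.translations(), tr, atol=1e-9)

    def test_rotations_and_timestamps_untouched(self):
        ts = np.arange(20) / 60.0
        rots = [_rz(5.0 * i) for i in range(20)]
        s = _stream(ts, np.random.default_rng(0).normal(size=(20, 3)), rots)
        out = savgol_translations(s, 7, 2)
        assert np.array_equal(out.timestamps, s.timestamps)
        for a, b in zip(out.poses, s.poses):
            assert np.array_equal(a.R, b.R)

    def test_window_too_large(self):
        s = _stream(np.arange(5) / 60.0, np.zeros((5, 3)))
        with pytest.raises(WindowTooLarge):
            savgol_translations(s, 7, 2)


class TestResample:
    def test_source_times_reproduced_exactly(self, rng):
        ts = np.arange(11) / 10.0
        s = _stream(ts, rng.normal(size=(11, 3)),
                    [RigidTransform.random(rng).R for _ in range(11)])
        out = resample(s, ts)
        for a, b in zip(out.poses, s.poses):
            assert a.is_close(b, atol=0.0)

    def test_slerp_midpoint_single_axis(self):
        s = _stream([0.0, 1.0], [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]],
                    [np.eye(3), _rz(90.0)])
        out = resample(s, [0.5])
        assert np.allclose(out.poses[0].R, _rz(45.0), atol=1e-9)
        assert np.allclose(out.poses[0].t, [1.0, 0.0, 0.0])

    def test_200hz_to_60hz_sample_count(self, rng):
        ts = np.arange(201) / 200.0
        s = _stream(ts, rng.normal(size=(201, 3)))
        target = np.arange(int(np.floor(1.0 * 60.0)) + 1) / 60.0
        out = resample(s, target)
        assert len(out) == 61

    def test_extrapolation_refused(self):
        s = _stream([0.0, 1.0], np.zeros((2, 3)))
        with pytest.raises(OutOfRange):
            resample(s, [1.5])

    def test_matches_scipy_slerp(self, rng):
        # independent cross-check of the quaternion interpolation path
        ts = np.array([0.0, 0.4, 1.0])
        rots = Rotation.from_rotvec(rng.normal(size=(3, 3)) * 0.5)
        s = _stream(ts, np.zeros((3, 3)), rots.as_matrix())
        tt = np.linspace(0.0, 1.0, 17)
        ours = resample(s, tt)
        ref = Slerp(ts, rots)(tt)
        for a, Rm in zip(ours.poses, ref.as_matrix()):
            assert np.allclose(a.R, Rm, atol=1e-9)


class TestKabschUmeyama:
    def test_identity(self, rng):
        P = rng.normal(size=(5, 3)) * 40.0
        assert kabsch_umeyama(P, P).is_close(RigidTransform.identity(), atol=1e-9)

    def test_exact_recovery(self, rng):
        P = rng.normal(size=(6, 3)) * 40.0
        G = RigidTransform.random(rng)
        T = kabsch_umeyama(P, G.apply(P))
        assert T.is_close(G, atol=1e-9)

    def test_local_optimality(self, rng):
        P = rng.normal(size=(8, 3)) * 30.0
        Q = RigidTransform.random(rng).apply(P) + rng.normal(size=(8, 3))
        T = kabsch_umeyama(P, Q)
        base = np.sum((T.apply(P) - Q) ** 2)
        for _ in range(1000):
            dT = RigidTransform.from_rotvec_trans(
                rng.normal(size=3) * 1e-3, rng.normal(size=3) * 1e-2)
            assert np.sum((dT.compose(T).apply(P) - Q) ** 2) >= base - 1e-12

    def test_never_a_reflection(self, rng):
        # near-planar sets tempt the SVD into a reflection; sign must be fixed
        P = rng.normal(size=(10, 3)) * np.array([30.0, 30.0, 1e-8])
        Q = -P[:, [1, 0, 2]]
        T = kabsch_umeyama(P, Q)
        assert np.linalg.det(T.R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_rejected(self):
        P = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=-1)
        with pytest.raises(DegenerateConfiguration):
            kabsch_umeyama(P, P)

    def test_matches_scipy_align_vectors(self, rng):
        P = rng.normal(size=(7, 3)) * 20.0
        Q = RigidTransform.random(rng).apply(P) + rng.normal(size=(7, 3)) * 0.5
        T = kabsch_umeyama(P, Q)
        R_sp, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert np.allclose(T.R, R_sp.as_matrix(), atol=1e-8)


class TestReferenceChain:
    def test_identity_world(self, rng):
        ts = np.arange(5) / 10.0
        s = _stream(ts, rng.normal(size=(5, 3)))
        out = reference_chain(RigidTransform.identity(), s)
        for a, b in zip(out.poses, s.poses):
            assert a.is_close(b)

    def test_chain_inverts(self, rng):
        ts = np.arange(5) / 10.0
        s = _stream(ts, rng.normal(size=(5, 3)),
                    [RigidTransform.random(rng).R for _ in range(5)])
        W = RigidTransform.random(rng)
        out = reference_chain(W, s)
        back = out.compose_left(W.invert())
        for a, b in zip(back.poses, s.poses):
            assert a.is_close(b, atol=1e-9)


class TestImageCornersAndMapping:
    def test_printed_corner_coordinates(self):
        c = image_corners(USImageSpec(fov=38.0, depth=30.0))
        assert np.allclose(c, [[19.0, 0.0, 0.0], [19.0, 30.0, 0.0],
                               [-19.0, 30.0, 0.0], [-19.0, 0.0, 0.0]])

    def test_degenerate_spec(self):
        assert np.allclose(image_corners(USImageSpec(fov=0.0, depth=0.0)), 0.0)

    def test_rectangle_area(self):
        c = image_corners(USImageSpec(fov=38.0, depth=30.0))
        area = np.linalg.norm(np.cross(c[1] - c[0], c[3] - c[0]))
        assert area == pytest.approx(38.0 * 30.0)

    def test_identity_poses_give_image_corners(self):
        s = _stream([0.0], [[0.0, 0.0, 0.0]])
        spec = USImageSpec()
        out = map_corners("concat", s, RigidTransform.identity(), spec)
        assert np.allclose(out[0], image_corners(spec))

    def test_origin_method_ignores_rotation(self, rng):
        R = RigidTransform.random(rng).R
        s = _stream([0.0], [[1.0, 2.0, 3.0]], [R])
        out = map_corners("origin", s)
        assert np.allclose(out, [[[1.0, 2.0, 3.0]]])

    def test_direct_equals_concat_for_same_pose(self, rng):
        T_probe = RigidTransform.random(rng, t_scale=30.0)
        T_dod = RigidTransform.random(rng, t_scale=50.0)
        s_dod = PoseStream(np.array([0.0]), (T_dod,))
        s_probe = PoseStream(np.array([0.0]), (T_dod.compose(T_probe),))
        spec = USImageSpec()
        a = map_corners("concat", s_dod, T_probe, spec)
        b = map_corners("direct", s_probe, None, spec)
        assert np.allclose(a, b, atol=1e-9)

    def test_map_image_pixels_corners_and_coplanarity(self, rng):
        spec = USImageSpec(fov=38.0, depth=30.0, pixel_size=38.0)
        pts = map_image_pixels(RigidTransform.identity(), None, spec, (2, 2))
        assert np.allclose(sorted(pts[:, 0].tolist()), [-19.0, -19.0, 19.0, 19.0])
        # coplanarity under an arbitrary pose
        spec2 = USImageSpec(pixel_size=1.0)
        pts2 = map_image_pixels(RigidTransform.random(rng), None, spec2, (10, 12))
        c = pts2 - pts2.mean(axis=0)
        assert np.linalg.svd(c, compute_uv=False)[2] < 1e-9


class TestErrorStats:
    def test_zero_error(self, rng):
        x = rng.normal(size=(30, 4, 3))
        st = error_stats(x, x)
        assert st.mean_norm == 0.0 and st.std_norm == 0.0
        assert np.all(st.mean == 0.0) and np.all(st.std == 0.0)

    def test_population_std_convention(self, rng):
        c = rng.normal(size=(50, 3))
        r = np.zeros((50, 3))
        st = error_stats(c, r)
        assert np.allclose(st.std, c.std(axis=0, ddof=0), atol=1e-12)
        assert st.n == 50

    def test_norms_are_euclidean_norms(self, rng):
        c, r = rng.normal(size=(40, 3)), rng.normal(size=(40, 3))
        st = error_stats(c, r)
        assert st.mean_norm == pytest.approx(np.linalg.norm(st.mean), abs=1e-12)
        assert st.std_norm == pytest.approx(np.linalg.norm(st.std), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatch):
            error_stats(np.zeros((3, 3)), np.zeros((4, 3)))
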