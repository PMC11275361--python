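"""Per-frame 6-DoF pose estimation from marker-corner correspondences.

The estimation scheme mirrors the tracking pipeline it serves:

1. the 2D-3D corner correspondences of all detected markers are augmented
   with one extra point per unordered marker pair — the midpoint of the two
   marker centres, taken consistently in the object frame and in the pixel
   frame (``u_avg = (u_i + u_j) / 2``);
2. an initial pose is found by RANSAC over P3P minimal solutions, selecting
   the largest consensus set under a pixel reprojection threshold;
3. the pose is refined by Levenberg-Marquardt minimization of the summed
   squared reprojection error over the RANSAC inliers only.

Two evaluation routes are provided: ``pose_concat`` estimates the
dodecahedron pose and concatenates the probe calibration matrix;
``pose_direct`` re-expresses the 3D corners in the probe frame first and
solves PnP for the probe pose directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateConfiguration, NoConsensus
from .geometry import CameraModel, DodecahedronModel, project
from .se3 import RigidTransform

_KABSCH_EPS = 1e-12


@dataclass(frozen=True)
class ObservationFrame:
    """Detected markers of one RGB frame."""

    timestamp: float
    detections: tuple  # of (marker_id, (4, 2) pixel corners)

    def __post_init__(self) -> None:
        ids = [d[0] for d in self.detections]
        if len(ids) != len(set(ids)):
            raise ValueError("marker ids must be unique within a frame")
        dets = tuple(
            (int(mid), np.asarray(px, dtype=float).reshape(4, 2))
            for mid, px in self.detections
        )
        object.__setattr__(self, "detections", dets)

    @property
    def marker_ids(self) -> list:
        return [d[0] for d in self.detections]


@dataclass
class CorrespondenceSet:
    """Matched 3D object-frame points (mm) and 2D pixel points."""

    points3d: np.ndarray             # (n, 3)
    points2d: np.ndarray             # (n, 2)
    origin_tags: np.ndarray          # (n,) 'corner' | 'augmented'
    marker_ids: np.ndarray           # (n,) owning marker id, -1 for augmented

    def __post_init__(self) -> None:
        self.points3d = np.asarray(self.points3d, dtype=float).reshape(-1, 3)
        self.points2d = np.asarray(self.points2d, dtype=float).reshape(-1, 2)
        self.origin_tags = np.asarray(self.origin_tags)
        self.marker_ids = np.asarray(self.marker_ids, dtype=int)
        n = len(self.points3d)
        if not (len(self.points2d) == len(self.origin_tags) == len(self.marker_ids) == n):
            raise ValueError("correspondence arrays must have equal lengths")

    def __len__(self) -> int:
        return len(self.points3d)

    @property
    def n_markers(self) -> int:
        return len(set(self.marker_ids[self.marker_ids >= 0].tolist()))


@dataclass(frozen=True)
class PoseEstimate:
    """Refined camera<-object pose with RANSAC bookkeeping."""

    T: RigidTransform
    inlier_mask: np.ndarray
    rms_reproj_px: float
    rms_initial_px: float = float("nan")
    ambiguous: bool = False


def build_correspondences(
    frame: ObservationFrame,
    points3d_by_id: dict,
) -> CorrespondenceSet:
    """Stack the per-marker (4, 3) object points against the detected pixels."""
    p3, p2, tags, mids = [], [], [], []
    for mid, px in frame.detections:
        obj = points3d_by_id[mid]
        p3.append(np.asarray(obj, float).reshape(4, 3))
        p2.append(px)
        tags.extend(["corner"] * 4)
        mids.extend([mid] * 4)
    if not p3:
        return CorrespondenceSet(
            np.empty((0, 3)), np.empty((0, 2)), np.empty(0, dtype=object),
            np.empty(0, dtype=int),
        )
    return CorrespondenceSet(
        np.concatenate(p3), np.concatenate(p2),
        np.array(tags, dtype=object), np.array(mids),
    )


def augment(corr: CorrespondenceSet) -> CorrespondenceSet:
    """Append the midpoint of each unordered marker-centre pair.

    With k detected markers this adds exactly k*(k-1)/2 points tagged
    ``augmented``; the original corner points are unchanged.  The 2D
    midpoint of the projected centres is not exactly the projection of the
    3D midpoint under perspective — the small mismatch is absorbed by the
    robust estimator downstream.
    """
    ids = sorted(set(corr.marker_ids[corr.marker_ids >= 0].tolist()))
    centers3, centers2 = {}, {}
    for mid in ids:
        m = corr.marker_ids == mid
        centers3[mid] = corr.points3d[m].mean(axis=0)
        centers2[mid] = corr.points2d[m].mean(axis=0)
    add3, add2 = [], []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            add3.append(0.5 * (centers3[ids[a]] + centers3[ids[b]]))
            add2.append(0.5 * (centers2[ids[a]] + centers2[ids[b]]))
    if not add3:
        return CorrespondenceSet(
            corr.points3d.copy(), corr.points2d.copy(),
            corr.origin_tags.copy(), corr.marker_ids.copy(),
        )
    n_add = len(add3)
    return CorrespondenceSet(
        np.concatenate([corr.points3d, np.asarray(add3)]),
        np.concatenate([corr.points2d, np.asarray(add2)]),
        np.concatenate([corr.origin_tags, np.array(["augmented"] * n_add, dtype=object)]),
        np.concatenate([corr.marker_ids, -np.ones(n_add, dtype=int)]),
    )


# ---------------------------------------------------------------------------
# minimal solver: P3P (Grunert's distance formulation)
# ---------------------------------------------------------------------------

def _rigid_fit(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping points P onto Q (Kabsch)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp, _validate=False)


def solve_p3p(obj_pts: np.ndarray, bearings: np.ndarray) -> list:
    """Poses consistent with 3 object points and their unit bearing vectors.

    Grunert's formulation: with camera-frame distances s1, s2, s3 to the
    three points, the laws of cosines give three quadratics; setting
    u = s2/s1, v = s3/s1 and eliminating u (it enters linearly in the
    difference of two ratio equations) leaves a quartic in v.  Each positive
    real root yields candidate distances, hence camera-frame points, and the
    pose follows from a rigid point-set fit.  Returns up to 4 candidates.
    """
    P1, P2, P3 = obj_pts
    a = np.linalg.norm(P2 - P3)
    b = np.linalg.norm(P1 - P3)
    c = np.linalg.norm(P1 - P2)
    if min(a, b, c) < 1e-9:
        return []
    j1, j2, j3 = bearings
    cos_a = float(j2 @ j3)
    cos_b = float(j1 @ j3)
    cos_g = float(j1 @ j2)

    a2, b2, c2 = a * a, b * b, c * c
    # E1: u^2 + v^2 - 2 u v cos_a - (a2/b2) (1 + v^2 - 2 v cos_b) = 0
    # E2: u^2 - 2 u cos_g + 1 - (c2/b2) (1 + v^2 - 2 v cos_b) = 0
    # E1 - E2 is linear in u:  A(v) u + B(v) = 0
    # A = 2 (cos_g - v cos_a)
    # B = v^2 - 1 + ((c2 - a2)/b2) (1 + v^2 - 2 v cos_b)
    # substitute u = -B/A into E2 and clear A^2:
    #   B^2 + 2 cos_g A B + C A^2 = 0,   C(v) = 1 - (c2/b2)(1 + v^2 - 2 v cos_b)
    r = (c2 - a2) / b2
    B_poly = np.array([1.0 + r, -2.0 * r * cos_b, r - 1.0])          # v^2, v, 1
    A_poly = np.array([-2.0 * cos_a, 2.0 * cos_g])
    C_poly = np.array([-c2 / b2, 2.0 * (c2 / b2) * cos_b, 1.0 - c2 / b2])
    quartic = np.polyadd(
        np.polyadd(np.polymul(B_poly, B_poly),
                   2.0 * cos_g * np.polymul(A_poly, B_poly)),
        np.polymul(C_poly, np.polymul(A_poly, A_poly)),
    )
    if np.max(np.abs(quartic)) < 1e-15:
        return []
    roots = np.roots(quartic)
    poses = []
    for v in roots:
        if abs(v.imag) > 1e-8 or v.real <= 0:
            continue
        v = float(v.real)
        A = 2.0 * (cos_g - v * cos_a)
        if abs(A) < 1e-12:
            continue
        B = v * v - 1.0 + r * (1.0 + v * v - 2.0 * v * cos_b)
        u = -B / A
        if u <= 0:
            continue
        denom = 1.0 + v * v - 2.0 * v * cos_b
        if denom <= 0:
            continue
        s1 = b / np.sqrt(denom)
        cam_pts = np.stack([s1 * j1, u * s1 * j2, v * s1 * j3])
        poses.append(_rigid_fit(obj_pts, cam_pts))
    return poses


def _reproj_residuals(
    x: np.ndarray, obj: np.ndarray, img: np.ndarray, camera: CameraModel
) -> np.ndarray:
    T = RigidTransform.from_rotvec_trans(x[:3], x[3:])
    pts_cam = T.apply(obj)
    z = np.clip(pts_cam[:, 2], 1e-6, None)
    xy = pts_cam[:, :2] / z[:, None]
    xyd = camera.distort_normalized(xy)
    px = np.stack([camera.fx * xyd[:, 0] + camera.cx,
                   camera.fy * xyd[:, 1] + camera.cy], axis=-1)
    return (px - img).ravel()


def _reproj_errors_px(
    T: RigidTransform, obj: np.ndarray, img: np.ndarray, camera: CameraModel
) -> np.ndarray:
    res = _reproj_residuals(
        np.concatenate([T.rotvec(), T.t]), obj, img, camera
    ).reshape(-1, 2)
    return np.linalg.norm(res, axis=1)


DEFAULT_PARAMS = {
    "ransac_iters": 500,
    "reproj_threshold_px": 2.0,
    "min_inliers": 4,
    "confidence": 0.99,
    "seed": 0,
}


def estimate_pose(
    corr: CorrespondenceSet, camera: CameraModel, params: dict | None = None
) -> PoseEstimate:
    """RANSAC + Levenberg-Marquardt pose from 2D-3D correspondences.

    Deterministic given ``params['seed']``.  Raises
    :class:`DegenerateConfiguration` for fewer than 4 or collinear points
    and :class:`NoConsensus` when no sampled model reaches the minimum
    inlier count.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    n = len(corr)
    if n < 4:
        raise DegenerateConfiguration(f"{n} correspondences; at least 4 required")
    sv = np.linalg.svd(corr.points3d - corr.points3d.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9:
        raise DegenerateConfiguration("3D points are collinear")

    obj, img = corr.points3d, corr.points2d
    norm_xy = camera.undistort_pixels(img)
    bearings = np.concatenate([norm_xy, np.ones((n, 1))], axis=1)
    bearings /= np.linalg.norm(bearings, axis=1, keepdims=True)

    rng = np.random.default_rng(p["seed"])
    thr = p["reproj_threshold_px"]
    best = None          # (n_inliers, -rms, mask, T)
    runner_up_T = None
    iters = int(p["ransac_iters"])
    i = 0
    while i < iters:
        i += 1
        idx = rng.choice(n, size=4, replace=False)
        tri = idx[:3]
        if np.linalg.matrix_rank(obj[tri] - obj[tri[0]]) < 2:
            continue
        for T in solve_p3p(obj[tri], bearings[tri]):
            if T.apply(obj[idx[3]])[2] <= 0:
                continue
            errs = _reproj_errors_px(T, obj, img, camera)
            mask = errs < thr
            n_in = int(mask.sum())
            if n_in < p["min_inliers"]:
                continue
            rms = float(np.sqrt(np.mean(errs[mask] ** 2)))
            key = (n_in, -rms)
            if best is None or key > (best[0], best[1]):
                if best is not None and not T.is_close(best[3], atol=1e-3):
                    runner_up_T = best[3]
                best = (n_in, -rms, mask, T)
                # adaptive iteration count (confidence-based early exit)
                w = n_in / n
                if w >= 1.0:
                    iters = i
                else:
                    denom = np.log(max(1e-12, 1.0 - w**4))
                    iters = min(iters, i + int(np.ceil(
                        np.log(1.0 - p["confidence"]) / denom)))
            elif runner_up_T is None and not T.is_close(best[3], atol=1e-3):
                runner_up_T = T
    if best is None:
        raise NoConsensus("no RANSAC model reached the minimum inlier count")

    _, _, mask, T0 = best
    rms0 = float(np.sqrt(np.mean(_reproj_errors_px(T0, obj, img, camera)[mask] ** 2)))

    # augmented midpoints are perspective-consistent only to first order
    # (~0.5 px mismatch at working distance); they support the consensus
    # stage but would bias the refinement, so LM sees inlier corners only
    fit_mask = mask & (corr.origin_tags == "corner")
    if fit_mask.sum() < 4:
        fit_mask = mask

    def refine(T_init: RigidTransform):
        x0 = np.concatenate([T_init.rotvec(), T_init.t])
        sol = least_squares(
            _reproj_residuals, x0, args=(obj[fit_mask], img[fit_mask], camera),
            method="lm", ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=100 * 7,
        )
        T = RigidTransform.from_rotvec_trans(sol.x[:3], sol.x[3:])
        rms = float(np.sqrt(np.mean(_reproj_errors_px(T, obj, img, camera)[mask] ** 2)))
        return T, rms

    T_ref, rms_ref = refine(T0)
    if rms_ref > rms0:          # LM must never worsen the inlier fit
        T_ref, rms_ref = T0, rms0

    # planar ambiguity: with a single marker (4 coplanar corners) two poses
    # can explain the data almost equally well — refine the runner-up too
    ambiguous = False
    if corr.n_markers <= 1 and runner_up_T is not None:
        T_alt, rms_alt = refine(runner_up_T)
        if rms_alt < rms_ref and not T_alt.is_close(T_ref, atol=1e-6):
            T_ref, T_alt = T_alt, T_ref
            rms_ref, rms_alt = rms_alt, rms_ref
        if rms_ref > 1e-12 and abs(rms_alt - rms_ref) / rms_ref < 0.05 \
                and T_ref.rotation_angle_to(T_alt) > 1e-3:
            ambiguous = True

    return PoseEstimate(
        T=T_ref, inlier_mask=mask, rms_reproj_px=rms_ref,
        rms_initial_px=rms0, ambiguous=ambiguous,
    )


def pose_concat(
    frame: ObservationFrame,
    model: DodecahedronModel,
    T_probe: RigidTransform,
    camera: CameraModel,
    params: dict | None = None,
):
    """Concatenation method: estimate T_cam2dod, then compose with T_probe.

    Returns ``(dod_estimate, T_cam2probe)``.
    """
    if not frame.detections:
        raise DegenerateConfiguration("empty frame")
    lut = {f.marker_id: f.corners_local for f in model.faces}
    corr = augment(build_correspondences(frame, lut))
    est = estimate_pose(corr, camera, params)
    return est, est.T.compose(T_probe)


def pose_direct(
    frame: ObservationFrame,
    model: DodecahedronModel,
    T_probe: RigidTransform,
    camera: CameraModel,
    params: dict | None = None,
) -> PoseEstimate:
    """Direct method: express corners in the probe frame, solve PnP once.

    The returned pose is T_cam2probe itself.
    """
    if not frame.detections:
        raise DegenerateConfiguration("empty frame")
    T_probe_inv = T_probe.invert()
    lut = {
        f.marker_id: T_probe_inv.apply(f.corners_local) for f in model.faces
    }
    corr = augment(build_correspondences(frame, lut))
    return estimate_pose(corr, camera, params)
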