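"""Trajectory post-processing and candidate-vs-reference evaluation.

The RGB tracker produces a 60 Hz pose stream; the infrared reference runs
at 200 Hz.  Evaluation therefore needs, in order: Savitzky-Golay smoothing
of the translation components, resampling of the reference onto the RGB
timestamps (SLERP for rotations, per-component linear interpolation for
translations), rigid registration of the IR marker observations
(Kabsch-Umeyama), mapping of the four ultrasound-image corners through each
transform chain, and per-axis mean/STD error statistics with their
Euclidean norms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateConfiguration,
    OutOfRange,
    ShapeMismatch,
    TimestampMismatch,
    WindowTooLarge,
)
from .se3 import RigidTransform, hemisphere_normalize, slerp


@dataclass(frozen=True)
class PoseStream:
    """Time-stamped sequence of rigid transforms."""

    timestamps: np.ndarray          # (n,) seconds, strictly increasing
    poses: tuple                    # n RigidTransforms
    rate_hint: float = 0.0          # Hz, informational

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float).reshape(-1)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "poses", tuple(self.poses))
        if len(ts) != len(self.poses):
            raise ValueError("timestamps and poses must have equal length")
        if len(ts) < 1:
            raise ValueError("stream must contain at least one sample")
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.poses)

    def translations(self) -> np.ndarray:
        return np.stack([p.t for p in self.poses])

    def quaternions(self) -> np.ndarray:
        """(n, 4) scalar-first quaternions, consecutively hemisphere-aligned."""
        Q = np.stack([p.as_quat_wxyz() for p in self.poses])
        for i in range(1, len(Q)):
            if Q[i] @ Q[i - 1] < 0:
                Q[i] = -Q[i]
        return Q

    def compose_left(self, T: RigidTransform) -> "PoseStream":
        """Apply a static transform on the left of every pose."""
        return PoseStream(
            self.timestamps.copy(),
            tuple(T.compose(p) for p in self.poses),
            self.rate_hint,
        )


@dataclass(frozen=True)
class USImageSpec:
    """Geometry of the (generic) B-mode image used for evaluation."""

    fov: float = 38.0          # mm, lateral field of view
    depth: float = 30.0        # mm, useful imaging depth
    pixel_size: float = 0.1    # mm / px

    def __post_init__(self) -> None:
        if self.fov < 0 or self.depth < 0:
            raise ValueError("fov and depth must be non-negative")


@dataclass(frozen=True)
class ErrorStats:
    """Per-axis mean/STD of signed corner errors plus Euclidean norms."""

    n: int
    mean: np.ndarray          # (3,) mm
    std: np.ndarray           # (3,) mm, population convention (1/N)
    mean_norm: float
    std_norm: float


def savgol_translations(stream: PoseStream, window: int = 15, polyorder: int = 3) -> PoseStream:
    """Savitzky-Golay smoothing of the translation components.

    Each translation component is filtered independently; rotations and
    timestamps pass through untouched.  Edges are handled by the filter's
    polynomial fit on the truncated window (scipy ``mode='interp'``).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window > len(stream):
        raise WindowTooLarge(f"window {window} exceeds stream length {len(stream)}")
    T = stream.translations()
    Tf = savgol_filter(T, window, polyorder, axis=0, mode="interp")
    poses = tuple(
        RigidTransform(p.R, tf, _validate=False)
        for p, tf in zip(stream.poses, Tf)
    )
    return PoseStream(stream.timestamps.copy(), poses, stream.rate_hint)


def resample(stream: PoseStream, target_times: np.ndarray) -> PoseStream:
    """Resample a pose stream at new timestamps inside its span.

    Rotations are interpolated by SLERP between the bracketing samples
    (quaternions hemisphere-aligned first); translations component-wise
    linearly.  A target time equal to a source time reproduces the source
    pose exactly.
    """
    tt = np.asarray(target_times, dtype=float).reshape(-1)
    ts = stream.timestamps
    if len(tt) and (tt.min() < ts[0] - 1e-12 or tt.max() > ts[-1] + 1e-12):
        raise OutOfRange(
            f"target times [{tt.min():.6f}, {tt.max():.6f}] outside source span "
            f"[{ts[0]:.6f}, {ts[-1]:.6f}]"
        )
    Q = stream.quaternions()
    T = stream.translations()
    poses = []
    idx = np.clip(np.searchsorted(ts, tt, side="right") - 1, 0, max(len(ts) - 2, 0))
    for t, i in zip(tt, idx):
        if len(ts) == 1:
            poses.append(stream.poses[0])
            continue
        t0, t1 = ts[i], ts[i + 1]
        a = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
        if a == 0.0:
            poses.append(stream.poses[i])
            continue
        if a == 1.0:
            poses.append(stream.poses[i + 1])
            continue
        q = slerp(Q[i], Q[i + 1], float(a))
        tr = (1.0 - a) * T[i] + a * T[i + 1]
        poses.append(RigidTransform.from_quat_trans(q, tr))
    return PoseStream(tt, tuple(poses), stream.rate_hint)


def kabsch_umeyama(P_local: np.ndarray, Q_observed: np.ndarray) -> RigidTransform:
    """Rigid transform (scale fixed at 1) minimizing sum ||T p_i - q_i||^2.

    Closed-form SVD solution of the orthogonal Procrustes problem with the
    reflection corrected through the sign of the smallest singular value, so
    the result is always a proper rotation.
    """
    P = np.asarray(P_local, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q_observed, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ShapeMismatch(f"{P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise DegenerateConfiguration("need at least 3 matched points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    if np.linalg.svd(Pc, compute_uv=False)[1] < 1e-9:
        raise DegenerateConfiguration("points are collinear")
    H = Pc.T @ Qc
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d if d != 0 else 1.0]) @ U.T
    return RigidTransform(R, cq - R @ cp, _validate=False)


def reference_chain(T_world2cam: RigidTransform, ir_stream: PoseStream) -> PoseStream:
    """Compose the static world<-camera pose with every sample.

    ``T_world2dod(t) = T_world2cam @ T_cam2dod_ir(t)`` with timestamps
    preserved.
    """
    return ir_stream.compose_left(T_world2cam)


def image_corners(spec: USImageSpec) -> np.ndarray:
    """The four ultrasound-image corners in the probe frame (mm).

    Probe frame: origin at the orthogonal projection of the transducer
    centre on the probe surface, y along the beam, x along the array,
    z = 0 in the image plane.  Order: (FOV/2, 0), (FOV/2, d), (-FOV/2, d),
    (-FOV/2, 0).
    """
    f, d = spec.fov / 2.0, spec.depth
    return np.array([
        [f, 0.0, 0.0],
        [f, d, 0.0],
        [-f, d, 0.0],
        [-f, 0.0, 0.0],
    ])


def map_corners(
    method: str,
    stream: PoseStream,
    T_probe: RigidTransform | None = None,
    spec: USImageSpec | None = None,
) -> np.ndarray:
    """Per-frame absolute corner positions for one evaluation route.

    * ``ref``    — poses are T_cam2dod from the IR reference; corners mapped
      through ``T_cam2dod @ T_probe``;
    * ``concat`` — poses are T_cam2dod from the RGB tracker; same chain;
    * ``direct`` — poses are T_cam2probe already; corners mapped directly;
    * ``origin`` — translation vector only (the rotational component of the
      final matrix is discarded); one point per frame.

    Returns (n_frames, 4, 3) for the corner methods, (n_frames, 1, 3) for
    ``origin``.
    """
    spec = spec or USImageSpec()
    if method == "origin":
        return stream.translations()[:, None, :]
    corners = image_corners(spec)
    if method in ("ref", "concat"):
        if T_probe is None:
            raise ValueError(f"method {method!r} requires T_probe")
        chains = [p.compose(T_probe) for p in stream.poses]
    elif method == "direct":
        chains = list(stream.poses)
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.stack([c.apply(corners) for c in chains])


def check_time_aligned(a: PoseStream, b: PoseStream, atol: float = 1e-9) -> None:
    if len(a) != len(b) or not np.allclose(a.timestamps, b.timestamps, atol=atol):
        raise TimestampMismatch("streams are not sampled at the same timestamps")


def error_stats(candidate: np.ndarray, reference: np.ndarray) -> ErrorStats:
    """Per-axis mean and population STD of signed corner errors.

    ``candidate`` and ``reference`` are matched (..., 3) corner-position
    arrays; the statistics are taken over all N corner points, and the norm
    columns are the Euclidean norms of the per-axis mean and STD vectors.
    """
    C = np.asarray(candidate, dtype=float).reshape(-1, 3)
    R = np.asarray(reference, dtype=float).reshape(-1, 3)
    if C.shape != R.shape:
        raise ShapeMismatch(f"{C.shape} vs {R.shape}")
    if len(C) < 1:
        raise ShapeMismatch("need at least one corner point")
    eps = C - R
    mean = eps.mean(axis=0)
    std = np.sqrt(np.mean((eps - mean) ** 2, axis=0))   # population (1/N)
    return ErrorStats(
        n=len(C),
        mean=mean,
        std=std,
        mean_norm=float(np.linalg.norm(mean)),
        std_norm=float(np.linalg.norm(std)),
    )


def map_image_pixels(
    pose: RigidTransform,
    T_probe: RigidTransform | None,
    spec: USImageSpec,
    grid: tuple,
) -> np.ndarray:
    """Map every pixel centre of an (rows x cols) image into 3D (mm).

    Pixel (r, c) sits at probe-frame ``(FOV/2 - c * pixel_size,
    r * pixel_size, 0)`` and is pushed through ``pose @ T_probe`` (or
    ``pose`` alone for a direct probe pose).  All mapped points of a single
    image are coplanar by construction.
    """
    rows, cols = grid
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts = np.stack([
        spec.fov / 2.0 - c * spec.pixel_size,
        r * spec.pixel_size,
        np.zeros_like(r, dtype=float),
    ], axis=-1).reshape(-1, 3)
    chain = pose.compose(T_probe) if T_probe is not None else pose
    return chain.apply(pts)
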