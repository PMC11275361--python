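"""Rigid-body transforms in SE(3).

Every frame-to-frame mapping in the pipeline (camera from dodecahedron,
dodecahedron from probe, world from camera, ...) is a :class:`RigidTransform`
holding a 3x3 rotation ``R`` and a translation ``t`` in millimetres.  The
4x4 homogeneous form exists only for serialization; invariants are enforced
on ``R`` and ``t`` directly.

Quaternions use scalar-first ``(w, x, y, z)`` order and are hemisphere
normalized on output: ``w >= 0``, and if ``w == 0`` the first nonzero
component is positive, so serialization is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import NotARotation

#: construction tolerance on ||R^T R - I||_max; loose enough for transforms
#: read back from 15-significant-digit text files
ORTHONORMALITY_TOL = 1e-6


def _check_rotation(R: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        raise NotARotation(f"rotation must be a finite 3x3 matrix, got shape {R.shape}")
    err = np.max(np.abs(R.T @ R - np.eye(3)))
    if err > tol:
        raise NotARotation(f"matrix is not orthonormal: ||R^T R - I||_max = {err:.3g}")
    if np.linalg.det(R) < 0:
        raise NotARotation("matrix is a reflection (det = -1), not a rotation")
    return R


def hemisphere_normalize(q: np.ndarray) -> np.ndarray:
    """Return q or -q such that w >= 0 (first nonzero component positive)."""
    q = np.asarray(q, dtype=float)
    for c in q:
        if c > 0.0:
            return q.copy()
        if c < 0.0:
            return -q
    return q.copy()


@dataclass(frozen=True)
class RigidTransform:
    """An element of SE(3): ``p' = R @ p + t`` with ``t`` in mm."""

    R: np.ndarray
    t: np.ndarray
    _validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self._validate:
            R = _check_rotation(self.R)
            t = np.asarray(self.t, dtype=float).reshape(3)
            if not np.all(np.isfinite(t)):
                raise NotARotation("translation must be finite")
        else:
            R = np.asarray(self.R, dtype=float)
            t = np.asarray(self.t, dtype=float).reshape(3)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        self.R.setflags(write=False)
        self.t.setflags(write=False)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3), _validate=False)

    @staticmethod
    def from_matrix(M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return RigidTransform(M[:3, :3], M[:3, 3])

    @staticmethod
    def from_quat_trans(q_wxyz: np.ndarray, t: np.ndarray) -> "RigidTransform":
        q = np.asarray(q_wxyz, dtype=float)
        R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
        return RigidTransform(R, t)

    @staticmethod
    def from_rotvec_trans(rotvec: np.ndarray, t: np.ndarray) -> "RigidTransform":
        return RigidTransform(
            Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
            t,
            _validate=False,
        )

    @staticmethod
    def random(rng: np.random.Generator, t_scale: float = 100.0) -> "RigidTransform":
        """Seeded random transform for tests and simulation plumbing."""
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        R = Rotation.from_quat(q).as_matrix()
        return RigidTransform(R, rng.uniform(-t_scale, t_scale, 3), _validate=False)

    # -- group operations --------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self @ other (apply ``other`` first, then ``self``)."""
        return RigidTransform(
            self.R @ other.R, self.R @ other.t + self.t, _validate=False
        )

    def invert(self) -> "RigidTransform":
        Rt = self.R.T
        return RigidTransform(Rt, -Rt @ self.t, _validate=False)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or an array of points (..., 3)."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.R.T + self.t

    # -- conversions -------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.t
        return M

    def as_quat_wxyz(self) -> np.ndarray:
        x, y, z, w = Rotation.from_matrix(self.R).as_quat()
        return hemisphere_normalize(np.array([w, x, y, z]))

    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.R).as_rotvec()

    def rotation_angle_to(self, other: "RigidTransform") -> float:
        """Geodesic angle (rad) between the two rotations."""
        return float(
            np.linalg.norm(
                Rotation.from_matrix(self.R.T @ other.R).as_rotvec()
            )
        )

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.R, other.R, atol=atol)
            and np.allclose(self.t, other.t, atol=atol)
        )


def make_transform(R: np.ndarray, t: np.ndarray) -> RigidTransform:
    """Validated constructor; raises :class:`NotARotation` on bad input."""
    return RigidTransform(R, t)


def compose(A: RigidTransform, B: RigidTransform) -> RigidTransform:
    return A.compose(B)


def invert(T: RigidTransform) -> RigidTransform:
    return T.invert()


def apply(T: RigidTransform, pts: np.ndarray) -> np.ndarray:
    return T.apply(pts)


def quat_to_rotation(q_wxyz: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) -> 3x3 rotation matrix."""
    q = np.asarray(q_wxyz, dtype=float)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"quaternion norm {n} deviates from 1 by more than 1e-9")
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


def rotation_to_quat(R: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix -> hemisphere-normalized quaternion (w, x, y, z)."""
    _check_rotation(R)
    x, y, z, w = Rotation.from_matrix(R).as_quat()
    return hemisphere_normalize(np.array([w, x, y, z]))


def slerp(q0_wxyz: np.ndarray, q1_wxyz: np.ndarray, alpha: float) -> np.ndarray:
    """Spherical linear interpolation along the shorter arc.

    q1 is flipped into q0's hemisphere before interpolating so the path is
    the shortest great-circle arc; the result is hemisphere normalized.
    """
    q0 = np.asarray(q0_wxyz, dtype=float)
    q1 = np.asarray(q1_wxyz, dtype=float)
    d = float(np.dot(q0, q1))
    if d < 0.0:
        q1 = -q1
        d = -d
    d = min(d, 1.0)
    theta = np.arccos(d)
    if theta < 1e-12:
        q = (1.0 - alpha) * q0 + alpha * q1  # nearly parallel: lerp
    else:
        s = np.sin(theta)
        q = (np.sin((1.0 - alpha) * theta) / s) * q0 + (np.sin(alpha * theta) / s) * q1
    return hemisphere_normalize(q / np.linalg.norm(q))
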