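"""Probe calibration from a crossed-wire phantom snapshot.

The phantom holds two wire layers in a known geometry: a proximal layer
where two wires cross at 8 mm depth, and a distal layer of ten parallel
wires at 18 mm depth spaced 4 mm apart.  A snapshot taken while only the
single proximal cross point is visible in the B-mode image fixes three
quantities at once:

* the rigid transform from the dodecahedron frame to the calibrator frame,
  ``T_dod2cal = T_cam2dod^-1 @ T_cam2cal`` (equivalently, the constraint
  ``T_cam2dod @ T_probe @ T_cam2cal^-1 = I``);
* the isotropic pixel size, from the known 4 mm spacing of the distal
  wire echoes;
* the in-plane 2D translation from the ultrasound-image origin to the
  calibrator origin (the wire cross), from the cross-echo pixel.

The calibrator frame is defined with its origin at the wire cross, y along
the beam (depth) direction and x along the transducer array, so the probe
calibration matrix maps ultrasound-image-frame millimetre coordinates into
the dodecahedron frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CollinearityViolation,
    DegenerateConfiguration,
    DepthInconsistent,
    SnapshotInvalid,
)
from .se3 import RigidTransform


@dataclass(frozen=True)
class CalibrationSnapshot:
    """One synchronized capture of cluster pose, calibrator pose and echoes."""

    T_cam2dod: RigidTransform
    T_cam2cal: RigidTransform
    cross_point_px: np.ndarray            # (2,) wire-cross echo pixel
    distal_wire_px: np.ndarray            # (n >= 2, 2) parallel-wire echo pixels
    proximal_depth: float = 8.0           # mm
    distal_depth: float = 18.0            # mm
    wire_spacing: float = 4.0             # mm
    image_width_px: int = 512
    multiple_proximal_echoes: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "cross_point_px",
                           np.asarray(self.cross_point_px, float).reshape(2))
        object.__setattr__(self, "distal_wire_px",
                           np.asarray(self.distal_wire_px, float).reshape(-1, 2))
        if len(self.distal_wire_px) < 2:
            raise DegenerateConfiguration("need at least 2 distal wire echoes")
        if not (0 < self.proximal_depth < self.distal_depth):
            raise ValueError("depths must be positive with distal > proximal")

    def to_json(self) -> dict:
        return {
            "T_cam2dod": {"quat": self.T_cam2dod.as_quat_wxyz().tolist(),
                          "t": self.T_cam2dod.t.tolist()},
            "T_cam2cal": {"quat": self.T_cam2cal.as_quat_wxyz().tolist(),
                          "t": self.T_cam2cal.t.tolist()},
            "cross_point_px": self.cross_point_px.tolist(),
            "distal_wire_px": self.distal_wire_px.tolist(),
            "proximal_depth": self.proximal_depth,
            "distal_depth": self.distal_depth,
            "wire_spacing": self.wire_spacing,
            "image_width_px": self.image_width_px,
            "multiple_proximal_echoes": self.multiple_proximal_echoes,
        }

    @staticmethod
    def from_json(obj: dict) -> "CalibrationSnapshot":
        return CalibrationSnapshot(
            T_cam2dod=RigidTransform.from_quat_trans(
                obj["T_cam2dod"]["quat"], obj["T_cam2dod"]["t"]),
            T_cam2cal=RigidTransform.from_quat_trans(
                obj["T_cam2cal"]["quat"], obj["T_cam2cal"]["t"]),
            cross_point_px=obj["cross_point_px"],
            distal_wire_px=obj["distal_wire_px"],
            proximal_depth=obj["proximal_depth"],
            distal_depth=obj["distal_depth"],
            wire_spacing=obj["wire_spacing"],
            image_width_px=int(obj.get("image_width_px", 512)),
            multiple_proximal_echoes=bool(obj.get("multiple_proximal_echoes", False)),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @staticmethod
    def load(path) -> "CalibrationSnapshot":
        return CalibrationSnapshot.from_json(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ProbeCalibration:
    """Output of the calibration: probe matrix + pixel size."""

    T_probe: RigidTransform      # ultrasound-image frame -> dodecahedron frame
    pixel_size: float            # mm / px, isotropic

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    def to_json(self) -> dict:
        return {"T_probe": {"quat": self.T_probe.as_quat_wxyz().tolist(),
                            "t": self.T_probe.t.tolist()},
                "pixel_size": self.pixel_size}

    @staticmethod
    def from_json(obj: dict) -> "ProbeCalibration":
        return ProbeCalibration(
            T_probe=RigidTransform.from_quat_trans(
                obj["T_probe"]["quat"], obj["T_probe"]["t"]),
            pixel_size=float(obj["pixel_size"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @staticmethod
    def load(path) -> "ProbeCalibration":
        return ProbeCalibration.from_json(json.loads(Path(path).read_text()))


def solve_probe_transform(
    T_cam2dod: RigidTransform, T_cam2cal: RigidTransform
) -> RigidTransform:
    """T_probe = T_cam2dod^-1 @ T_cam2cal (calibrator frame -> dodecahedron)."""
    return T_cam2dod.invert().compose(T_cam2cal)


def estimate_pixel_scale(distal_wire_px: np.ndarray, wire_spacing: float = 4.0) -> float:
    """mm/px from the equally spaced distal-wire echoes.

    The echoes are fitted to a 1D lattice along their principal axis; the
    scale is the physical wire spacing over the mean adjacent pixel gap.
    Echoes straying off the line by more than 10% of the mean gap raise
    :class:`CollinearityViolation`.
    """
    P = np.asarray(distal_wire_px, dtype=float).reshape(-1, 2)
    if len(P) < 2:
        raise DegenerateConfiguration("need at least 2 distal wire echoes")
    c = P.mean(axis=0)
    U, s, Vt = np.linalg.svd(P - c)
    axis = Vt[0]
    along = (P - c) @ axis
    perp = (P - c) @ Vt[1]
    order = np.argsort(along)
    gaps = np.diff(along[order])
    mean_gap = float(np.mean(gaps))
    if mean_gap <= 0:
        raise DegenerateConfiguration("coincident echoes")
    if np.max(np.abs(perp)) > 0.10 * mean_gap:
        raise CollinearityViolation(
            f"perpendicular residual {np.max(np.abs(perp)):.3g} px exceeds 10% of "
            f"the mean gap {mean_gap:.3g} px"
        )
    return wire_spacing / mean_gap


def image_origin_offset(
    cross_point_px: np.ndarray,
    pixel_size: float,
    proximal_depth: float = 8.0,
    image_center_u: float = 256.0,
    tolerance: float = 1.0,
) -> np.ndarray:
    """In-plane (x, y) mm offset of the wire cross in the ultrasound frame.

    The ultrasound-image origin sits at the top-centre of the image (skin
    surface under the transducer centre); x is lateral, y is depth.  The
    depth implied by the cross pixel must agree with the nominal proximal
    depth within ``tolerance`` mm.
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    u, v = np.asarray(cross_point_px, float).reshape(2)
    x = (u - image_center_u) * pixel_size
    y = v * pixel_size
    if abs(y - proximal_depth) > tolerance:
        raise DepthInconsistent(
            f"cross depth {y:.2f} mm vs nominal {proximal_depth:.2f} mm"
        )
    return np.array([x, y])


def calibrate(snapshot: CalibrationSnapshot) -> ProbeCalibration:
    """Full probe calibration from one snapshot.

    Composes the dodecahedron->calibrator solve with the in-plane offset of
    the ultrasound-image origin (embedded as a z = 0 translation), yielding
    the matrix that maps image-frame mm coordinates into the dodecahedron
    frame.  Snapshots flagged with multiple proximal echoes (probe pitched
    or rolled off the wire plane) are refused.
    """
    if snapshot.multiple_proximal_echoes:
        raise SnapshotInvalid(
            "multiple proximal echoes: probe not aligned with the wire cross"
        )
    T_dod2cal = solve_probe_transform(snapshot.T_cam2dod, snapshot.T_cam2cal)
    pixel_size = estimate_pixel_scale(snapshot.distal_wire_px, snapshot.wire_spacing)
    offset = image_origin_offset(
        snapshot.cross_point_px, pixel_size, snapshot.proximal_depth,
        image_center_u=snapshot.image_width_px / 2.0,
    )
    # p_cal = p_us - offset, so (us -> cal) is a pure translation by -offset
    T_cal_from_us = RigidTransform(np.eye(3), -np.array([offset[0], offset[1], 0.0]),
                                   _validate=False)
    return ProbeCalibration(
        T_probe=T_dod2cal.compose(T_cal_from_us), pixel_size=pixel_size
    )
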