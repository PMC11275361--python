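"""On-disk formats: pose CSV, observation JSON-lines, JSON configs, PLY.

Units on disk are always millimetres and seconds; rotations are serialized
as hemisphere-normalized scalar-first quaternions.  All floats are written
at 15 significant digits so write/read round-trips are lossless to 1e-12.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateMarkerId,
    MalformedHeader,
    MalformedRecord,
    NonMonotoneTimestamps,
)
from .pose import ObservationFrame
from .se3 import RigidTransform
from .trajectory import PoseStream

POSE_CSV_COLUMNS = ["t", "tx", "ty", "tz", "qw", "qx", "qy", "qz"]


def write_pose_csv(stream: PoseStream, path) -> None:
    rows = []
    Q = [p.as_quat_wxyz() for p in stream.poses]
    for t, p, q in zip(stream.timestamps, stream.poses, Q):
        rows.append([t, *p.t, *q])
    df = pd.DataFrame(rows, columns=POSE_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.15g")


def read_pose_csv(path) -> PoseStream:
    df = pd.read_csv(path)
    if list(df.columns) != POSE_CSV_COLUMNS:
        raise MalformedHeader(
            f"expected columns {POSE_CSV_COLUMNS}, got {list(df.columns)}"
        )
    ts = df["t"].to_numpy(dtype=float)
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise NonMonotoneTimestamps("timestamps must be strictly increasing")
    poses = []
    for _, row in df.iterrows():
        q = np.array([row.qw, row.qx, row.qy, row.qz])
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            warnings.warn(
                f"quaternion norm drift {abs(n - 1.0):.3g} at t={row.t}; renormalizing",
                stacklevel=2,
            )
        poses.append(RigidTransform.from_quat_trans(q / n, [row.tx, row.ty, row.tz]))
    if not poses:
        return _EmptyPoseStream()
    return PoseStream(ts, tuple(poses))


class _EmptyPoseStream:
    """Zero-length stand-in returned for a header-only CSV."""

    timestamps = np.empty(0)
    poses = ()

    def __len__(self) -> int:
        return 0


def write_observations_jsonl(frames, path) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            rec = {
                "t": fr.timestamp,
                "detections": [
                    {"id": mid, "corners": np.asarray(px).tolist()}
                    for mid, px in fr.detections
                ],
            }
            fh.write(json.dumps(rec) + "\n")


def read_observations_jsonl(path) -> tuple:
    frames = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            t = float(rec["t"])
            dets = [(int(d["id"]), np.asarray(d["corners"], float).reshape(4, 2))
                    for d in rec["detections"]]
        except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
            raise MalformedRecord(f"line {ln}: {exc}") from exc
        ids = [d[0] for d in dets]
        if len(ids) != len(set(ids)):
            raise DuplicateMarkerId(f"line {ln}: repeated marker id")
        frames.append(ObservationFrame(timestamp=t, detections=tuple(dets)))
    return tuple(frames)


def write_ir_csv(ir_stream, path) -> None:
    """IR marker stream: t, marker_index, x, y, z (world frame, mm)."""
    rows = []
    for t, pts in zip(ir_stream.timestamps, ir_stream.positions):
        for k, p in enumerate(pts):
            rows.append([t, k, *p])
    pd.DataFrame(rows, columns=["t", "marker_index", "x", "y", "z"]).to_csv(
        path, index=False, float_format="%.15g")


def read_ir_csv(path):
    from .synthetic import IRStream

    df = pd.read_csv(path)
    times = np.sort(df["t"].unique())
    n_m = int(df["marker_index"].max()) + 1
    pos = np.empty((len(times), n_m, 3))
    for i, t in enumerate(times):
        sub = df[df["t"] == t].sort_values("marker_index")
        pos[i] = sub[["x", "y", "z"]].to_numpy()
    return IRStream(timestamps=times, positions=pos)


def write_corners_csv(corners: np.ndarray, timestamps: np.ndarray, path) -> None:
    """Corner trajectories: t, corner_index, x, y, z."""
    rows = []
    for t, frame in zip(timestamps, corners):
        for k, p in enumerate(np.atleast_2d(frame)):
            rows.append([t, k, *p])
    pd.DataFrame(rows, columns=["t", "corner_index", "x", "y", "z"]).to_csv(
        path, index=False, float_format="%.15g")


def write_ply(points: np.ndarray, path) -> None:
    """Minimal ASCII PLY point-cloud export."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
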