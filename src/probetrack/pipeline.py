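"""End-to-end evaluation pipeline: track -> filter -> align -> statistics.

`run_pipeline` mirrors the desk experiment: per-frame pose estimation from
the RGB observations (direct and/or concatenation route), Savitzky-Golay
smoothing of the translations, recovery of the reference trajectory from
the IR marker stream by per-sample rigid registration, resampling of the
200 Hz reference onto the tracker's 60 Hz timestamps, mapping of the four
ultrasound-image corners through every chain, and per-axis mean/STD error
statistics with Euclidean norms (one report row per route, matching the
results-table layout).

Frames where pose estimation fails are carried as gaps: their timestamps
simply drop out of the candidate stream, and the reference is resampled
only at the surviving timestamps.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .calibration import ProbeCalibration
from .errors import ProbeTrackError
from .geometry import CameraModel, DodecahedronModel
from .pose import pose_concat, pose_direct
from .se3 import RigidTransform
from .synthetic import IRStream, SimConfig, ir_reference_poses
from .trajectory import (
    PoseStream,
    USImageSpec,
    error_stats,
    map_corners,
    resample,
    savgol_translations,
)

log = logging.getLogger("probetrack")


@dataclass
class PipelineConfig:
    method: str = "both"            # direct | concat | both
    savgol_window: int = 15
    savgol_polyorder: int = 3
    resample_rate: float = 60.0
    us_spec: USImageSpec = field(default_factory=USImageSpec)
    pose_params: dict = field(default_factory=dict)
    include_origin: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("direct", "concat", "both"):
            raise ValueError("method must be direct, concat or both")


def _stats_to_row(stats) -> dict:
    return {
        "n": stats.n,
        "mean": [float(v) for v in stats.mean],
        "mean_norm": stats.mean_norm,
        "std": [float(v) for v in stats.std],
        "std_norm": stats.std_norm,
    }


def track_frames(
    frames,
    model: DodecahedronModel,
    calibration: ProbeCalibration,
    camera: CameraModel,
    method: str,
    pose_params: dict | None = None,
    seed: int = 0,
):
    """Estimate the probe pose in every frame; failed frames become gaps.

    Returns ``(stream, n_failed)`` where the stream holds T_cam2probe for
    the ``direct`` method and T_cam2dod for ``concat``.
    """
    params = dict(pose_params or {})
    params.setdefault("seed", seed)
    ts, poses = [], []
    n_failed = 0
    for fr in frames:
        try:
            if method == "direct":
                est = pose_direct(fr, model, calibration.T_probe, camera, params)
                T = est.T
            else:
                est, _ = pose_concat(fr, model, calibration.T_probe, camera, params)
                T = est.T
        except ProbeTrackError:
            n_failed += 1
            continue
        ts.append(fr.timestamp)
        poses.append(T)
    if not poses:
        raise ProbeTrackError("pose estimation failed on every frame")
    return PoseStream(np.array(ts), tuple(poses), 0.0), n_failed


def run_pipeline(
    frames,
    ir_stream: IRStream,
    sim_config: SimConfig,
    calibration: ProbeCalibration,
    pipeline: PipelineConfig | None = None,
) -> dict:
    """Execute the full evaluation and return the report dictionary.

    ``frames`` are the RGB observations, ``ir_stream`` the raw IR marker
    positions; ``sim_config`` supplies the camera, cluster geometry, IR
    cluster layout and static world<-camera pose (for real recordings these
    would come from configuration files instead).
    """
    cfg = pipeline or PipelineConfig()
    report: dict = {"rows": {}, "timing_s": {}, "n_frames": len(frames)}
    methods = ["direct", "concat"] if cfg.method == "both" else [cfg.method]

    t0 = time.perf_counter()
    ref_full = ir_reference_poses(ir_stream, sim_config)   # T_cam2dod at 200 Hz
    report["timing_s"]["reference"] = time.perf_counter() - t0

    for method in methods:
        t0 = time.perf_counter()
        cand, n_failed = track_frames(
            frames, sim_config.model, calibration, sim_config.camera,
            method, cfg.pose_params, cfg.seed,
        )
        report["timing_s"][f"track_{method}"] = time.perf_counter() - t0
        report.setdefault("n_failed", {})[method] = n_failed
        log.info("%s: tracked %d frames, %d gaps", method, len(cand), n_failed)

        window = cfg.savgol_window
        if window > len(cand):       # short runs: shrink to the largest odd fit
            window = len(cand) if len(cand) % 2 else len(cand) - 1
        if window > cfg.savgol_polyorder:
            cand = savgol_translations(cand, window, cfg.savgol_polyorder)

        keep = (cand.timestamps >= ref_full.timestamps[0]) & \
               (cand.timestamps <= ref_full.timestamps[-1])
        cand = PoseStream(cand.timestamps[keep],
                          tuple(p for p, k in zip(cand.poses, keep) if k))
        ref = resample(ref_full, cand.timestamps)

        ref_corners = map_corners("ref", ref, calibration.T_probe, cfg.us_spec)
        if method == "direct":
            cand_corners = map_corners("direct", cand, None, cfg.us_spec)
        else:
            cand_corners = map_corners("concat", cand, calibration.T_probe,
                                       cfg.us_spec)
        report["rows"][method] = _stats_to_row(error_stats(cand_corners, ref_corners))

        if cfg.include_origin:
            # dodecahedron-origin route: translation only, no rotation
            if method == "concat":
                cand_orig = map_corners("origin", cand)
                ref_orig = map_corners("origin", ref)
                report["rows"]["origin"] = _stats_to_row(
                    error_stats(cand_orig, ref_orig))
    return report


def format_report(report: dict) -> str:
    """Human-readable table mirroring the results layout."""
    lines = [
        f"{'Method':<14}{'mean x':>9}{'mean y':>9}{'mean z':>9}{'|mean|':>9}"
        f"{'std x':>9}{'std y':>9}{'std z':>9}{'|std|':>9}   [mm]"
    ]
    for name, row in report["rows"].items():
        m, s = row["mean"], row["std"]
        lines.append(
            f"{name:<14}{m[0]:>9.3f}{m[1]:>9.3f}{m[2]:>9.3f}{row['mean_norm']:>9.3f}"
            f"{s[0]:>9.3f}{s[1]:>9.3f}{s[2]:>9.3f}{row['std_norm']:>9.3f}"
        )
    return "\n".join(lines)
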