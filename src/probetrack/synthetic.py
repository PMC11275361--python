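"""Seeded simulator of probe sweeps, RGB marker observations and IR streams.

The generator emulates the desk setup the tracker is meant for: a probe
carrying the marker dodecahedron sweeps slowly (roughly constant velocity,
gentle orientation changes) in front of a static RGB camera at 60 Hz, while
an infrared motion-capture system observes a rigid IR-marker cluster on the
same body at 200 Hz in its own world frame.  Observations carry isotropic
Gaussian pixel noise and Bernoulli per-marker dropout (RGB) and Gaussian
millimetre noise (IR).  Everything is a pure function of (config, seed).

What is NOT modelled: motion blur, rolling shutter, lighting, detector
failure beyond dropout, clock drift (an optional constant offset exists),
soft-tissue contact forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation, RotationSpline

from .calibration import CalibrationSnapshot
from .geometry import CameraModel, DodecahedronModel, IRClusterModel, \
    build_dodecahedron, project, visible_markers
from .pose import ObservationFrame
from .se3 import RigidTransform
from .trajectory import PoseStream, kabsch_umeyama


def default_camera() -> CameraModel:
    """720p pinhole with a mid-range focal length and no distortion."""
    return CameraModel(fx=900.0, fy=900.0, cx=640.0, cy=360.0,
                       dist=np.zeros(5), width=1280, height=720)


def default_world2cam() -> RigidTransform:
    """Static mocap-world <- camera pose used by the simulated IR system."""
    R = Rotation.from_euler("xyz", [10.0, 25.0, -5.0], degrees=True).as_matrix()
    return RigidTransform(R, np.array([500.0, 300.0, 1000.0]))


@dataclass(frozen=True)
class SimConfig:
    duration: float = 5.0              # s
    rgb_rate: float = 60.0             # Hz
    ir_rate: float = 200.0             # Hz
    camera: CameraModel = field(default_factory=default_camera)
    model: DodecahedronModel = field(default_factory=build_dodecahedron)
    ir_cluster: IRClusterModel = field(
        default_factory=IRClusterModel.default_tetrahedron)
    T_probe_true: RigidTransform = field(
        default_factory=lambda: RigidTransform(
            Rotation.from_euler("xyz", [90.0, 0.0, 15.0], degrees=True).as_matrix(),
            np.array([5.0, -30.0, 45.0]),
        ))
    T_world2cam: RigidTransform = field(default_factory=default_world2cam)
    camera_distance: float = 400.0     # mm, mean cluster depth
    sweep_extent: float = 50.0         # mm, lateral sweep length
    wobble_mm: float = 3.0             # mm, random waypoint jitter
    max_ang_vel_dps: float = 30.0      # deg/s cap on angular velocity
    pixel_noise_px: float = 0.0        # sigma of corner pixel noise
    ir_noise_mm: float = 0.0           # sigma of IR marker noise
    dropout_prob: float = 0.0          # per-marker per-frame
    clock_offset_s: float = 0.0        # IR clock minus RGB clock
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rgb_rate <= 0 or self.ir_rate <= 0:
            raise ValueError("duration and rates must be positive")
        if self.pixel_noise_px < 0 or self.ir_noise_mm < 0:
            raise ValueError("noise sigmas must be non-negative")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must be in [0, 1)")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class IRStream:
    """Raw simulated motion-capture output: marker positions in world mm."""

    timestamps: np.ndarray        # (n_t,)
    positions: np.ndarray         # (n_t, n_markers, 3)


@dataclass(frozen=True)
class SimOutput:
    config: SimConfig
    truth_rgb: PoseStream         # T_cam2dod at the RGB timestamps
    truth_ir: PoseStream          # T_cam2dod at the IR timestamps
    rgb_frames: tuple             # ObservationFrames
    ir_stream: IRStream


class TrajectoryEvaluator:
    """C2-smooth 6-DoF path t -> T_cam2dod, evaluable at any t in [0, T]."""

    def __init__(self, config: SimConfig):
        rng = np.random.default_rng(config.seed)
        dt_way = 0.5
        n_way = max(int(np.ceil(config.duration / dt_way)) + 1, 2)
        t_way = np.linspace(0.0, config.duration, n_way)
        # translation: steady lateral sweep plus small seeded wobble
        base = np.array([0.0, 0.0, config.camera_distance])
        sweep = np.linspace(-config.sweep_extent / 2.0,
                            config.sweep_extent / 2.0, n_way)
        way_t = base + np.stack([
            sweep + rng.normal(0.0, config.wobble_mm, n_way),
            rng.normal(0.0, config.wobble_mm, n_way),
            rng.normal(0.0, config.wobble_mm, n_way),
        ], axis=-1)
        # rotation: small-angle random walk, step bounded well under the cap
        cap_rad = np.deg2rad(config.max_ang_vel_dps)
        step_max = 0.4 * cap_rad * dt_way
        rots = [Rotation.identity()]
        for _ in range(n_way - 1):
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            ang = rng.uniform(0.2, 1.0) * step_max
            rots.append(Rotation.from_rotvec(ang * ax) * rots[-1])
        self._duration = config.duration
        self._tspline = CubicSpline(t_way, way_t, axis=0, bc_type="natural")
        self._rspline = RotationSpline(t_way, Rotation.concatenate(rots))

    def __call__(self, t: float) -> RigidTransform:
        t = float(np.clip(t, 0.0, self._duration))
        return RigidTransform(
            self._rspline(t).as_matrix(), self._tspline(t), _validate=False
        )

    def sample(self, times: np.ndarray, rate_hint: float = 0.0) -> PoseStream:
        return PoseStream(
            np.asarray(times, float),
            tuple(self(t) for t in np.asarray(times, float)),
            rate_hint,
        )

    def angular_speed(self, t: float) -> float:
        """rad/s from the rotation spline's analytic angular rate."""
        return float(np.linalg.norm(self._rspline(t, 1)))


def _grid(duration: float, rate: float) -> np.ndarray:
    n = int(np.floor(duration * rate)) + 1
    return np.arange(n) / rate


def simulate_trajectory(config: SimConfig) -> TrajectoryEvaluator:
    """Build the continuous ground-truth path for a configuration."""
    return TrajectoryEvaluator(config)


def simulate_observations(
    truth: TrajectoryEvaluator, config: SimConfig
) -> tuple:
    """RGB observation frames at ``rgb_rate`` with noise and dropout."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    frames = []
    for t in _grid(config.duration, config.rgb_rate):
        T = truth(t)
        dets = []
        for mid in sorted(visible_markers(config.camera, T, config.model)):
            if config.dropout_prob > 0 and rng.random() < config.dropout_prob:
                continue
            px = project(config.camera, T, config.model.face_by_id(mid).corners_local)
            if config.pixel_noise_px > 0:
                px = px + rng.normal(0.0, config.pixel_noise_px, px.shape)
            dets.append((mid, px))
        frames.append(ObservationFrame(timestamp=t, detections=tuple(dets)))
    return tuple(frames)


def simulate_ir_stream(truth: TrajectoryEvaluator, config: SimConfig) -> IRStream:
    """IR marker positions (world frame, mm) at ``ir_rate`` with noise."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    times = _grid(config.duration, config.ir_rate)
    P = config.ir_cluster.points_local
    out = np.empty((len(times), len(P), 3))
    for i, t in enumerate(times):
        T_world2dod = config.T_world2cam.compose(truth(t))
        out[i] = T_world2dod.apply(P)
    if config.ir_noise_mm > 0:
        out = out + rng.normal(0.0, config.ir_noise_mm, out.shape)
    return IRStream(timestamps=times + config.clock_offset_s, positions=out)


def ir_reference_poses(ir: IRStream, config: SimConfig) -> PoseStream:
    """Recover T_cam2dod from the IR stream by rigid registration per sample."""
    T_cam_from_world = config.T_world2cam.invert()
    poses = []
    for obs in ir.positions:
        T_world2dod = kabsch_umeyama(config.ir_cluster.points_local, obs)
        poses.append(T_cam_from_world.compose(T_world2dod))
    return PoseStream(ir.timestamps - config.clock_offset_s, tuple(poses),
                      config.ir_rate)


def simulate(config: SimConfig) -> SimOutput:
    """Full simulation: truth streams, RGB frames and IR stream."""
    truth = simulate_trajectory(config)
    return SimOutput(
        config=config,
        truth_rgb=truth.sample(_grid(config.duration, config.rgb_rate),
                               config.rgb_rate),
        truth_ir=truth.sample(_grid(config.duration, config.ir_rate),
                              config.ir_rate),
        rgb_frames=simulate_observations(truth, config),
        ir_stream=simulate_ir_stream(truth, config),
    )


def simulate_calibration_snapshot(
    config: SimConfig,
    T_cam2dod: RigidTransform | None = None,
    pixel_size: float = 0.1,
    cross_lateral_mm: float = 0.0,
    image_width_px: int = 512,
    echo_noise_px: float = 0.0,
) -> CalibrationSnapshot:
    """Consistent crossed-wire snapshot for the ground-truth probe matrix.

    Places the wire-cross echo at the nominal 8 mm proximal depth and ten
    distal echoes spaced (4 mm / pixel_size) pixels apart at 18 mm, and
    derives the calibrator pose from ``T_probe_true`` so that the
    calibration solve round-trips exactly in the noiseless case.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    if T_cam2dod is None:
        T_cam2dod = simulate_trajectory(config)(0.0)
    offset = np.array([cross_lateral_mm, 8.0, 0.0])
    T_cam2cal = T_cam2dod.compose(config.T_probe_true).compose(
        RigidTransform(np.eye(3), offset, _validate=False))
    center_u = image_width_px / 2.0
    cross_px = np.array([center_u + cross_lateral_mm / pixel_size,
                         8.0 / pixel_size])
    gap = 4.0 / pixel_size
    us = center_u + (np.arange(10) - 4.5) * gap
    distal = np.stack([us, np.full(10, 18.0 / pixel_size)], axis=-1)
    if echo_noise_px > 0:
        cross_px = cross_px + rng.normal(0.0, echo_noise_px, 2)
        distal = distal + rng.normal(0.0, echo_noise_px, distal.shape)
    return CalibrationSnapshot(
        T_cam2dod=T_cam2dod,
        T_cam2cal=T_cam2cal,
        cross_point_px=cross_px,
        distal_wire_px=distal,
        image_width_px=image_width_px,
    )
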