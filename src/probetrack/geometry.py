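"""Marker-cluster geometry and the pinhole camera.

The tracked target is a regular dodecahedron carrying one square ArUco
marker per face (12 markers).  Marker squares sit in the face plane with
one side parallel to a face edge at a fixed perpendicular inset.  The
cluster frame has its origin at the solid centroid; corner coordinates are
in millimetres.

The camera is a standard pinhole with Brown-Conrady distortion
(k1, k2, p1, p2, k3); frame convention x right, y down, z forward, pixel
origin at the top-left pixel centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BehindCamera, MarkerDoesNotFit, UnknownMarkerId
from .se3 import RigidTransform

GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

#: inradius of a regular dodecahedron with unit edge: (1/2)*sqrt((25+11*sqrt(5))/10)
INRADIUS_PER_EDGE = 0.5 * np.sqrt((25.0 + 11.0 * np.sqrt(5.0)) / 10.0)


# ---------------------------------------------------------------------------
# camera
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with Brown-Conrady distortion."""

    fx: float
    fy: float
    cx: float
    cy: float
    dist: np.ndarray = field(default_factory=lambda: np.zeros(5))
    width: int = 1280
    height: int = 720

    def __post_init__(self) -> None:
        object.__setattr__(self, "dist", np.asarray(self.dist, dtype=float).reshape(5))
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    # -- distortion model --------------------------------------------------
    def distort_normalized(self, xy: np.ndarray) -> np.ndarray:
        x, y = xy[..., 0], xy[..., 1]
        k1, k2, p1, p2, k3 = self.dist
        r2 = x * x + y * y
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        return np.stack([xd, yd], axis=-1)

    def undistort_pixels(self, px: np.ndarray, iters: int = 20) -> np.ndarray:
        """Pixel coordinates -> ideal normalized image coordinates.

        Inverts the Brown-Conrady model by fixed-point iteration, which
        converges for the mild distortions of factory-calibrated lenses.
        """
        px = np.asarray(px, dtype=float)
        xd = np.stack([(px[..., 0] - self.cx) / self.fx,
                       (px[..., 1] - self.cy) / self.fy], axis=-1)
        x = xd.copy()
        for _ in range(iters):
            d = self.distort_normalized(x)
            x = x + (xd - d)
        return x

    def to_json(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "dist": list(map(float, self.dist)),
            "width": self.width, "height": self.height,
        }

    @staticmethod
    def from_json(obj: dict) -> "CameraModel":
        return CameraModel(
            fx=obj["fx"], fy=obj["fy"], cx=obj["cx"], cy=obj["cy"],
            dist=np.asarray(obj.get("dist", np.zeros(5)), dtype=float),
            width=int(obj["width"]), height=int(obj["height"]),
        )


def project(camera: CameraModel, T_cam_from_obj: RigidTransform, pts: np.ndarray) -> np.ndarray:
    """Project object-frame 3D points (mm) to pixel coordinates.

    Raises :class:`BehindCamera` if any point has camera-frame z <= 0.
    """
    pts_cam = T_cam_from_obj.apply(np.asarray(pts, dtype=float))
    z = pts_cam[..., 2]
    if np.any(z <= 0.0):
        raise BehindCamera("point(s) at non-positive depth")
    xy = pts_cam[..., :2] / z[..., None]
    xyd = camera.distort_normalized(xy)
    return np.stack([camera.fx * xyd[..., 0] + camera.cx,
                     camera.fy * xyd[..., 1] + camera.cy], axis=-1)


# ---------------------------------------------------------------------------
# dodecahedron cluster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Face:
    marker_id: int
    corners_local: np.ndarray      # (4, 3) marker corner coordinates, mm
    outward_normal: np.ndarray     # unit vector
    center: np.ndarray             # face (pentagon) centroid, mm
    vertex_indices: tuple          # pentagon vertex indices, CCW from outside


@dataclass(frozen=True)
class DodecahedronModel:
    edge_length: float
    marker_size: float
    marker_inset: float
    faces: tuple  # 12 Face entries

    @property
    def marker_ids(self) -> list:
        return [f.marker_id for f in self.faces]

    def face_by_id(self, marker_id: int) -> Face:
        for f in self.faces:
            if f.marker_id == marker_id:
                return f
        raise UnknownMarkerId(marker_id)

    def all_corners(self) -> np.ndarray:
        """(48, 3) stacked marker corners in face order."""
        return np.concatenate([f.corners_local for f in self.faces], axis=0)

    def to_json(self) -> dict:
        return {
            "edge_length": self.edge_length,
            "marker_size": self.marker_size,
            "marker_inset": self.marker_inset,
            "faces": [
                {
                    "marker_id": int(f.marker_id),
                    "corners_local": f.corners_local.tolist(),
                    "outward_normal": f.outward_normal.tolist(),
                    "center": f.center.tolist(),
                }
                for f in self.faces
            ],
        }

    @staticmethod
    def from_json(obj: dict) -> "DodecahedronModel":
        faces = tuple(
            Face(
                marker_id=int(f["marker_id"]),
                corners_local=np.asarray(f["corners_local"], dtype=float),
                outward_normal=np.asarray(f["outward_normal"], dtype=float),
                center=np.asarray(f["center"], dtype=float),
                vertex_indices=(),
            )
            for f in obj["faces"]
        )
        return DodecahedronModel(
            edge_length=float(obj["edge_length"]),
            marker_size=float(obj["marker_size"]),
            marker_inset=float(obj["marker_inset"]),
            faces=faces,
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @staticmethod
    def load(path) -> "DodecahedronModel":
        return DodecahedronModel.from_json(json.loads(Path(path).read_text()))


def _dodecahedron_vertices(edge_length: float) -> np.ndarray:
    """The 20 vertices, lexicographically sorted for a deterministic indexing."""
    phi = GOLDEN
    V = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                V.append((sx, sy, sz))
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            V.append((0.0, s1 / phi, s2 * phi))
            V.append((s1 / phi, s2 * phi, 0.0))
            V.append((s1 * phi, 0.0, s2 / phi))
    V = np.array(sorted(V))
    # edge of the canonical construction is 2/phi; rescale to requested edge
    return V * (edge_length / (2.0 / phi))


def _face_normals() -> np.ndarray:
    """12 outward unit face normals (icosahedron vertex directions), sorted."""
    phi = GOLDEN
    N = []
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            N.append((0.0, s1 * phi, s2))
            N.append((s1 * phi, s2, 0.0))
            N.append((s1, 0.0, s2 * phi))
    N = np.array(sorted(N))
    return N / np.linalg.norm(N, axis=1, keepdims=True)


def _regular_pentagon_2d(edge: float) -> np.ndarray:
    """Pentagon vertices (CCW) with one edge on y = -apothem, centred at 0."""
    R = edge / (2.0 * np.sin(np.pi / 5.0))
    ang = -np.pi / 2.0 + np.pi / 5.0 + 2.0 * np.pi * np.arange(5) / 5.0
    return np.stack([R * np.cos(ang), R * np.sin(ang)], axis=-1)


def _point_in_convex_polygon(poly: np.ndarray, p: np.ndarray, margin: float = 1e-9) -> bool:
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        edge = b - a
        # CCW polygon: interior is to the left of each edge
        cross = edge[0] * (p[1] - a[1]) - edge[1] * (p[0] - a[0])
        if cross < margin:
            return False
    return True


def build_dodecahedron(
    edge_length: float = 31.0,
    marker_size: float = 25.0,
    marker_inset: float = 2.5,
    id_assignment=None,
) -> DodecahedronModel:
    """Construct the 12-marker dodecahedron cluster model.

    The marker square sits in its face plane, lower side parallel to the
    face's canonical edge at perpendicular distance ``marker_inset``,
    centred laterally on the edge midpoint.  The canonical edge is the one
    whose (sorted) vertex-index pair is lexicographically smallest under the
    deterministic vertex enumeration, so identical inputs give bit-identical
    corner tables.

    Corner order is the ArUco convention: clockwise from top-left as seen
    from outside the solid.
    """
    if id_assignment is None:
        id_assignment = list(range(12))
    id_assignment = list(id_assignment)
    if len(id_assignment) != 12 or len(set(id_assignment)) != 12:
        raise ValueError("id_assignment must be 12 distinct integers")

    # fit check in the canonical 2D pentagon
    pent = _regular_pentagon_2d(edge_length)
    apothem = edge_length / (2.0 * np.tan(np.pi / 5.0))
    s, inset = marker_size, marker_inset
    square2d = np.array([
        [-s / 2.0, -apothem + inset + s],   # top-left
        [s / 2.0, -apothem + inset + s],    # top-right
        [s / 2.0, -apothem + inset],        # bottom-right
        [-s / 2.0, -apothem + inset],       # bottom-left
    ])
    if not all(_point_in_convex_polygon(pent, c) for c in square2d):
        raise MarkerDoesNotFit(
            f"a {marker_size} mm square with {marker_inset} mm inset does not fit "
            f"a pentagon of edge {edge_length} mm"
        )

    V = _dodecahedron_vertices(edge_length)
    normals = _face_normals()
    inradius = edge_length * INRADIUS_PER_EDGE

    faces = []
    for face_idx, n in enumerate(normals):
        d = V @ n
        idx = np.where(d > inradius - 1e-9 * edge_length)[0]
        assert len(idx) == 5, "each face plane must contain exactly 5 vertices"
        center = V[idx].mean(axis=0)
        # order pentagon vertices CCW as seen from outside (looking against n)
        e1 = V[idx[0]] - center
        e1 -= n * (e1 @ n)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        ang = np.arctan2((V[idx] - center) @ e2, (V[idx] - center) @ e1)
        order = idx[np.argsort(ang)]
        # canonical edge: lexicographically smallest sorted index pair
        pairs = [tuple(sorted((order[i], order[(i + 1) % 5]))) for i in range(5)]
        k = min(range(5), key=lambda i: pairs[i])
        va, vb = sorted(pairs[k])
        edge_mid = 0.5 * (V[va] + V[vb])
        x_f = V[vb] - V[va]
        x_f /= np.linalg.norm(x_f)
        y_f = np.cross(n, x_f)
        if (center - edge_mid) @ y_f < 0:     # y must point edge -> interior
            x_f = -x_f
            y_f = -y_f
        # marker square in 3D; clockwise from top-left seen from outside
        corners = np.stack([
            edge_mid + x_f * (-s / 2.0) + y_f * (inset + s),
            edge_mid + x_f * (s / 2.0) + y_f * (inset + s),
            edge_mid + x_f * (s / 2.0) + y_f * inset,
            edge_mid + x_f * (-s / 2.0) + y_f * inset,
        ])
        faces.append(Face(
            marker_id=id_assignment[face_idx],
            corners_local=corners,
            outward_normal=n.copy(),
            center=center,
            vertex_indices=tuple(int(i) for i in order),
        ))
    return DodecahedronModel(edge_length, marker_size, marker_inset, tuple(faces))


def marker_corners_local(model: DodecahedronModel, marker_id: int) -> np.ndarray:
    """(4, 3) corners of one marker, clockwise from top-left (outside view)."""
    return model.face_by_id(marker_id).corners_local.copy()


def visible_markers(
    camera: CameraModel,
    T_cam_from_dod: RigidTransform,
    model: DodecahedronModel,
) -> set:
    """Marker ids visible under self-occlusion and image-bounds tests.

    A marker counts as visible iff its face is front-facing (outward normal
    in camera coordinates makes an obtuse angle with the viewing ray to the
    face centre) and all four projected corners land inside the image.
    """
    centroid_z = T_cam_from_dod.apply(np.zeros(3))[2]
    if centroid_z <= 0:
        raise BehindCamera("cluster centroid behind the camera")
    out = set()
    for f in model.faces:
        n_cam = T_cam_from_dod.R @ f.outward_normal
        c_cam = T_cam_from_dod.apply(f.center)
        if n_cam @ c_cam >= 0.0:
            continue
        corners_cam = T_cam_from_dod.apply(f.corners_local)
        if np.any(corners_cam[:, 2] <= 0.0):
            continue
        px = project(camera, RigidTransform.identity(), corners_cam)
        inside = (
            (px[:, 0] >= 0) & (px[:, 0] <= camera.width - 1)
            & (px[:, 1] >= 0) & (px[:, 1] <= camera.height - 1)
        )
        if np.all(inside):
            out.add(f.marker_id)
    return out


# ---------------------------------------------------------------------------
# IR reference cluster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IRClusterModel:
    """Retro-reflective marker cluster rigidly attached to the dodecahedron."""

    points_local: np.ndarray         # (n >= 3, 3) mm, cluster frame
    labels: tuple = ()

    def __post_init__(self) -> None:
        P = np.asarray(self.points_local, dtype=float)
        object.__setattr__(self, "points_local", P)
        if P.shape[0] < 3:
            raise ValueError("IR cluster needs at least 3 markers")
        s = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
        if s[1] < 1e-6:
            raise ValueError("IR cluster markers are collinear")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"ir{i}" for i in range(P.shape[0]))
            )

    @staticmethod
    def default_tetrahedron(circumradius: float = 40.0) -> "IRClusterModel":
        """4 markers at tetrahedral positions (circumradius in mm)."""
        P = np.array([
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]) / np.sqrt(3.0) * circumradius
        return IRClusterModel(P)
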