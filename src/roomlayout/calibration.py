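"""Single-image self-calibration from two orthogonal pairs of ground-parallel lines.

Two annotated pairs of parallel, ground-level 3D directions give two
vanishing points V1 and V2; the line through them is the horizon H.  With
the principal point O at the image center and zero skew/yaw/translation,
orthogonality of the two directions fixes the focal length:

    f^2 = -(V1 - O) . (V2 - O) = h^2 - |O Oh|^2,   h^2 = |Oh V1| |Oh V2|,

where Oh is the foot of the perpendicular from O onto H.  The vanishing
point Vs of the straight-ahead direction is the intersection of H with the
vertical line through O, its orthogonal partner Vc satisfies
|Oh Vc| = h^2 / |Oh Vs| on the opposite side of Oh, and the rotation
columns r1 = K^-1 Vc / |.|, r3 = K^-1 Vs / |.| yield pitch and roll.

Sign conventions (fixed so the synthetic forward model round-trips):
positive pitch raises the optical axis (horizon below center in y-down
pixels); positive roll rotates r1 = (cos roll, -sin roll, 0).  The camera
rotation is the Euler product R = Rx(pitch) Rz(roll), under which Vs lies
exactly on the vertical line through O for any roll.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    DEFAULT_PARALLEL_TOL_DEG,
    DegenerateAnnotationError,
    HomoPoint2D,
    ImageFrame,
    InconsistentAnnotationError,
    LineSegment2D,
    foot_of_perpendicular,
    intersect,
    intersect_lines,
    line_direction,
    line_through,
    signed_coordinate,
)

__all__ = [
    "CalibrationAnnotation",
    "VanishingGeometry",
    "CameraModel",
    "build_vanishing_geometry",
    "geometry_from_vps",
    "estimate_focal",
    "locate_axis_vps",
    "recover_pose",
    "locate_v3",
    "calibrate",
]


@dataclass(frozen=True)
class CalibrationAnnotation:
    """Two pairs of ground-parallel segments, the pairs orthogonal in 3D."""

    pair_u: tuple[LineSegment2D, LineSegment2D]
    pair_v: tuple[LineSegment2D, LineSegment2D]
    frame: ImageFrame

    def translated(self, offset) -> "CalibrationAnnotation":
        return CalibrationAnnotation(
            tuple(s.translated(offset) for s in self.pair_u),
            tuple(s.translated(offset) for s in self.pair_v),
            self.frame,
        )


@dataclass(frozen=True)
class VanishingGeometry:
    """Projective skeleton of one image, in centered coordinates.

    ``u_dir`` is the unit direction along the horizon (oriented toward
    positive x); ``u1``/``u2`` are the signed coordinates of V1/V2 along it,
    measured from Oh.
    """

    frame: ImageFrame
    v1: HomoPoint2D
    v2: HomoPoint2D
    horizon: np.ndarray
    oh: np.ndarray
    u_dir: np.ndarray
    u1: float
    u2: float
    h: float

    @property
    def o_oh(self) -> float:
        """Distance from the principal point to the horizon."""
        return float(np.hypot(*self.oh))

    def horizon_coordinate(self, p: HomoPoint2D) -> float:
        """Signed coordinate of a point on H along ``u_dir`` from Oh."""
        return signed_coordinate(p, self.oh, self.u_dir)

    def point_on_horizon(self, u: float) -> HomoPoint2D:
        if math.isinf(u):
            d = self.u_dir if u > 0 else -self.u_dir
            return HomoPoint2D.at_infinity(*d)
        return HomoPoint2D.finite(*(self.oh + u * self.u_dir))


def geometry_from_vps(v1: HomoPoint2D, v2: HomoPoint2D, frame: ImageFrame) -> VanishingGeometry:
    """Build the projective skeleton from two vanishing points (centered coords)."""
    if v1.is_infinite and v2.is_infinite:
        raise DegenerateAnnotationError(
            "both vanishing points at infinity: no perspective information"
        )
    if v1.is_infinite or v2.is_infinite:
        raise InconsistentAnnotationError(
            "a vanishing point at infinity leaves the focal length indeterminate"
        )
    horizon = line_through(v1, v2)
    oh = foot_of_perpendicular(horizon)
    u_dir = line_direction(horizon)
    u1 = float((v1.xy - oh) @ u_dir)
    u2 = float((v2.xy - oh) @ u_dir)
    if u1 * u2 >= 0.0:
        raise InconsistentAnnotationError(
            "V1 and V2 lie on the same side of Oh: orthogonal ground directions "
            "cannot produce this geometry (f^2 would be non-positive)"
        )
    h = math.sqrt(-u1 * u2)
    return VanishingGeometry(frame, v1, v2, horizon, oh, u_dir, u1, u2, h)


def build_vanishing_geometry(
    annot: CalibrationAnnotation,
    tol_parallel_deg: float = DEFAULT_PARALLEL_TOL_DEG,
) -> VanishingGeometry:
    """Intersect the annotated pairs and assemble the vanishing geometry."""
    frame = annot.frame

    def centered_vp(pair) -> HomoPoint2D:
        vp = intersect_lines(pair[0], pair[1], tol_parallel_deg)
        if vp.is_infinite:
            return vp
        return HomoPoint2D.finite(*frame.to_centered(vp.xy))

    v1 = centered_vp(annot.pair_u)
    v2 = centered_vp(annot.pair_v)
    return geometry_from_vps(v1, v2, frame)


def estimate_focal(geom: VanishingGeometry, frame: ImageFrame | None = None) -> float:
    """Focal length in pixels from the orthogonal vanishing-point pair."""
    f_sq = geom.h**2 - geom.o_oh**2
    # Cross-check against the direct dot-product form; both derive from the
    # same orthogonality constraint and must agree to rounding error.
    f_sq_dot = -float(geom.v1.xy @ geom.v2.xy)
    if not math.isclose(f_sq, f_sq_dot, rel_tol=1e-9, abs_tol=1e-6):
        raise InconsistentAnnotationError("internal focal-length forms disagree")
    if f_sq <= 0.0:
        raise InconsistentAnnotationError("h^2 <= |OOh|^2: no real focal length")
    return math.sqrt(f_sq)


def locate_axis_vps(
    geom: VanishingGeometry, frame: ImageFrame | None = None
) -> tuple[HomoPoint2D, HomoPoint2D]:
    """Vanishing points of the straight-ahead (Vs) and left-right (Vc) axes.

    Vs is the intersection of the vertical line through O with H.  Vc sits on
    H at |Oh Vc| = h^2/|Oh Vs| on the opposite side of Oh; with zero roll
    (Vs = Oh) it is the point at infinity along H.
    """
    vertical = np.array([1.0, 0.0, 0.0])  # x = 0 in centered coords
    vs = intersect(vertical, geom.horizon)
    if vs.is_infinite:
        raise InconsistentAnnotationError("vertical horizon: roll of 90 degrees")
    us = geom.horizon_coordinate(vs)
    if us == 0.0:
        vc = HomoPoint2D.at_infinity(*geom.u_dir)
    else:
        vc = geom.point_on_horizon(-geom.h**2 / us)
    return vs, vc


def _k_inv_unit(p: HomoPoint2D, f: float) -> np.ndarray:
    """Unit camera-frame direction K^-1 p / |K^-1 p| for a (possibly infinite) point."""
    if p.is_infinite:
        v = np.array([p.v[0], p.v[1], 0.0])
    else:
        v = np.array([p.xy[0], p.xy[1], f])
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class CameraModel:
    """Intrinsics and self-pose of a single view (zero skew, yaw, translation)."""

    frame: ImageFrame
    focal_length_px: float
    pitch_deg: float
    roll_deg: float
    rotation: np.ndarray  # columns r1 (right), r2 (down), r3 (forward)

    def __post_init__(self) -> None:
        if self.focal_length_px <= 0:
            raise ValueError("focal length must be positive")
        R = self.rotation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must have determinant +1")

    @property
    def fov_h_deg(self) -> float:
        """Horizontal field of view, 2 atan(W / 2f)."""
        return 2.0 * math.degrees(math.atan(self.frame.width_px / (2.0 * self.focal_length_px)))

    def project_direction(self, d_world) -> HomoPoint2D:
        """Centered image point of a world direction (vanishing point)."""
        d = self.rotation @ np.asarray(d_world, dtype=float)
        if d[2] < 0:
            d = -d
        f = self.focal_length_px
        if d[2] == 0.0:
            return HomoPoint2D.at_infinity(d[0], d[1])
        return HomoPoint2D.finite(f * d[0] / d[2], f * d[1] / d[2])


def rotation_from_angles(pitch_deg: float, roll_deg: float) -> np.ndarray:
    """World-to-camera rotation R = Rx(pitch) Rz(roll); columns are world axes."""
    th, ro = math.radians(pitch_deg), math.radians(roll_deg)
    rx = np.array(
        [[1, 0, 0], [0, math.cos(th), math.sin(th)], [0, -math.sin(th), math.cos(th)]]
    )
    rz = np.array(
        [[math.cos(ro), math.sin(ro), 0], [-math.sin(ro), math.cos(ro), 0], [0, 0, 1]]
    )
    return rx @ rz


def recover_pose(geom: VanishingGeometry, f: float, frame: ImageFrame | None = None) -> CameraModel:
    """Rotation, pitch and roll from the axis vanishing points and f."""
    frame = frame or geom.frame
    vs, vc = locate_axis_vps(geom)
    r3 = _k_inv_unit(vs, f)
    if r3[2] < 0:
        r3 = -r3
    r1 = _k_inv_unit(vc, f)
    if r1[0] < 0:
        r1 = -r1
    if r1[0] == 0.0:
        raise InconsistentAnnotationError("left-right axis projects vertically: roll of 90 degrees")
    cross = np.cross(r1, r3)
    if np.linalg.norm(cross) < 1e-12:
        raise DegenerateAnnotationError("degenerate rotation: r1 parallel to r3")
    # r1 and r3 are orthogonal by construction of Vc; tidy up rounding.
    r1 = r1 - (r1 @ r3) * r3
    r1 /= np.linalg.norm(r1)
    r2 = np.cross(r3, r1)
    rotation = np.column_stack([r1, r2, r3])
    pitch = math.degrees(math.atan2(r3[1], r3[2]))
    roll = math.degrees(math.atan2(-r1[1], r2[1]))
    return CameraModel(frame, float(f), pitch, roll, rotation)


def locate_v3(geom: VanishingGeometry, frame: ImageFrame | None = None) -> HomoPoint2D:
    """Vertical vanishing point: O is the orthocenter of triangle V1 V2 V3.

    V3 lies on the perpendicular from O to H, at the position where
    (O - V1) . (V3 - V2) = 0.  When H passes through O the altitude never
    re-crosses and V3 is at infinity along the perpendicular.
    """
    v1, v2 = geom.v1.xy, geom.v2.xy
    n = np.array([-geom.u_dir[1], geom.u_dir[0]])  # unit normal to H
    denom = float(-v1 @ n)
    f_sq = float(-v1 @ v2)
    if denom == 0.0:
        # |OOh| = 0: horizon through the principal point.
        return HomoPoint2D.at_infinity(*n)
    s = f_sq / denom
    return HomoPoint2D.finite(*(s * n))


def calibrate(
    annot: CalibrationAnnotation,
    tol_parallel_deg: float = DEFAULT_PARALLEL_TOL_DEG,
) -> tuple[VanishingGeometry, CameraModel]:
    """Full calibration: vanishing geometry, focal length and self-pose."""
    geom = build_vanishing_geometry(annot, tol_parallel_deg)
    f = estimate_focal(geom)
    return geom, recover_pose(geom, f)
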