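"""Room-layout outlining, rasterization, wall orientations and the aerial view.

Given the calibrated vanishing geometry plus one annotated wall (its
ground-parallel edge L1 with endpoints at the wall-wall corners, and its
vertical extent L2), the Manhattan prerequisites make every layout
boundary a straight line through a known vanishing point:

* Va = L1 x H is the vanishing point of the annotated wall's horizontal
  edge direction; the ceiling/floor conjunctions of that wall run from Va
  through the endpoints of L2.
* The wall-wall conjunctions are vertical, so they run from V3 through
  the endpoints of L1; their intersections with the ceiling/floor
  conjunctions are the corners p2, p3 (top) and p6, p7 (bottom).
* The orthogonal side walls' edge direction vanishes at Vo, the point on
  H with |Oh Vo| = h^2 / |Oh Va| on the opposite side of Oh; their
  ceiling/floor conjunctions run from Vo through p2/p6 (left) and p3/p7
  (right), clipped to the image boundary (p1, p5, p4, p8).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .calibration import CameraModel, VanishingGeometry, locate_axis_vps, locate_v3
from .geometry import (
    HomoPoint2D,
    ImageFrame,
    LineSegment2D,
    clip_segment_to_box,
    foot_of_perpendicular,
    intersect,
    line_direction,
    line_through,
)

__all__ = [
    "WallPosition",
    "WallAnnotation",
    "LayoutCorners",
    "LayoutSegmentation",
    "AerialWallSpec",
    "InvalidCornerSetError",
    "outline_walls",
    "rasterize_segmentation",
    "wall_orientations",
    "build_aerial_view",
    "pixel_error",
]

LABEL_UNKNOWN, LABEL_CEILING, LABEL_FLOOR, LABEL_FIRST_WALL = 0, 1, 2, 3


class InvalidCornerSetError(ValueError):
    """Corner set implies self-intersecting or otherwise impossible regions."""


class WallPosition(str, Enum):
    LEFT = "left"
    MIDDLE = "middle"
    RIGHT = "right"


@dataclass(frozen=True)
class WallAnnotation:
    """One annotated side wall: edge line L1, height line L2, position tag."""

    l1: LineSegment2D
    l2: LineSegment2D
    position: WallPosition = WallPosition.MIDDLE

    def translated(self, offset) -> "WallAnnotation":
        return WallAnnotation(self.l1.translated(offset), self.l2.translated(offset), self.position)


@dataclass(frozen=True)
class LayoutCorners:
    """Reconstructed layout skeleton (centered coordinates).

    ``p1..p8`` follow the top (p1-p4) and bottom (p5-p8) polylines left to
    right; outer corners are None when the construction skips them (the
    inner corner already lies on or beyond the image edge).  ``lines``
    holds the eight homogeneous boundary lines used by the rasterizer.
    """

    frame: ImageFrame
    position: WallPosition
    va: HomoPoint2D
    vo: HomoPoint2D
    v3: HomoPoint2D
    p1: np.ndarray | None
    p2: HomoPoint2D
    p3: HomoPoint2D
    p4: np.ndarray | None
    p5: np.ndarray | None
    p6: HomoPoint2D
    p7: HomoPoint2D
    p8: np.ndarray | None
    lines: dict = field(repr=False, default_factory=dict)


def outline_walls(
    wall: WallAnnotation, geom: VanishingGeometry, frame: ImageFrame | None = None
) -> LayoutCorners:
    """Outline the annotated wall and its orthogonal neighbours."""
    frame = frame or geom.frame
    v3 = locate_v3(geom)

    # Annotation endpoints in centered coordinates, normalised so that
    # L1 runs left to right and L2 top (ceiling) to bottom (floor).
    l1a, l1b = (frame.to_centered(p) for p in (wall.l1.a, wall.l1.b))
    if l1b[0] < l1a[0]:
        l1a, l1b = l1b, l1a
    l2a, l2b = (frame.to_centered(p) for p in (wall.l2.a, wall.l2.b))
    if l2b[1] < l2a[1]:
        l2a, l2b = l2b, l2a
    l1_left, l1_right = HomoPoint2D.finite(*l1a), HomoPoint2D.finite(*l1b)
    l2_top, l2_bot = HomoPoint2D.finite(*l2a), HomoPoint2D.finite(*l2b)

    va = intersect(line_through(l1_left, l1_right), geom.horizon)
    u_a = geom.horizon_coordinate(va)
    if math.isinf(u_a):
        vo = HomoPoint2D.finite(*geom.oh)  # frontal annotated wall
    elif u_a == 0.0:
        vo = HomoPoint2D.at_infinity(*geom.u_dir)
    else:
        vo = geom.point_on_horizon(-geom.h**2 / u_a)

    ceil_mid = line_through(va, l2_top)
    floor_mid = line_through(va, l2_bot)
    left_sep = line_through(v3, l1_left)
    right_sep = line_through(v3, l1_right)

    p2 = intersect(left_sep, ceil_mid)
    p3 = intersect(right_sep, ceil_mid)
    p6 = intersect(left_sep, floor_mid)
    p7 = intersect(right_sep, floor_mid)

    ceil_left = line_through(vo, p2)
    floor_left = line_through(vo, p6)
    ceil_right = line_through(vo, p3)
    floor_right = line_through(vo, p7)

    bounds = frame.bounds_centered

    def outer_corner(inner: HomoPoint2D, line: np.ndarray, leftward: bool) -> np.ndarray | None:
        """March from an inner corner along its conjunction line to the frame edge."""
        if inner.is_infinite:
            return None
        x, y = inner.xy
        xmin, xmax, ymin, ymax = bounds
        if not (xmin < x < xmax and ymin < y < ymax):
            return None  # inner corner on/off the image edge: step skipped
        d = line_direction(line)
        if leftward:
            d = -d
        return clip_segment_to_box(inner.xy, d, bounds)

    p1 = outer_corner(p2, ceil_left, leftward=True)
    p5 = outer_corner(p6, floor_left, leftward=True)
    p4 = outer_corner(p3, ceil_right, leftward=False)
    p8 = outer_corner(p7, floor_right, leftward=False)

    lines = {
        "left_sep": left_sep,
        "right_sep": right_sep,
        "ceil_mid": ceil_mid,
        "floor_mid": floor_mid,
        "ceil_left": ceil_left,
        "floor_left": floor_left,
        "ceil_right": ceil_right,
        "floor_right": floor_right,
    }
    return LayoutCorners(
        frame, wall.position, va, vo, v3, p1, p2, p3, p4, p5, p6, p7, p8, lines
    )


@dataclass(frozen=True)
class LayoutSegmentation:
    """Per-pixel layout labels: 0 unknown, 1 ceiling, 2 floor, 3+ walls left to right."""

    labels: np.ndarray
    legend: dict[int, str]
    wall_slots: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D raster")

    @property
    def frame(self) -> ImageFrame:
        h, w = self.labels.shape
        return ImageFrame(w, h)

    @property
    def n_walls(self) -> int:
        return int(sum(1 for k in self.legend if k >= LABEL_FIRST_WALL))

    def mirrored(self) -> "LayoutSegmentation":
        """Horizontal mirror: flip the raster and reverse the wall label order."""
        flipped = self.labels[:, ::-1].copy()
        walls = sorted(k for k in self.legend if k >= LABEL_FIRST_WALL)
        remap = {old: walls[len(walls) - 1 - i] for i, old in enumerate(walls)}
        out = flipped.copy()
        for old, new in remap.items():
            out[flipped == old] = new
        slot_mirror = {"left": "right", "middle": "middle", "right": "left"}
        slots = {remap[k]: slot_mirror[v] for k, v in self.wall_slots.items()}
        return LayoutSegmentation(out, dict(self.legend), slots)


def _base_legend() -> dict[int, str]:
    return {LABEL_UNKNOWN: "unknown", LABEL_CEILING: "ceiling", LABEL_FLOOR: "floor"}


def segmentation_from_labels(labels: np.ndarray, wall_slots: dict[int, str] | None = None) -> LayoutSegmentation:
    """Wrap a raw label raster, building the legend from the labels present."""
    legend = _base_legend()
    for k in sorted(int(v) for v in np.unique(labels) if v >= LABEL_FIRST_WALL):
        legend[k] = f"side wall {k - LABEL_FIRST_WALL + 1}"
    return LayoutSegmentation(np.asarray(labels, dtype=np.uint8), legend, wall_slots or {})


def rasterize_segmentation(corners: LayoutCorners, frame: ImageFrame | None = None) -> LayoutSegmentation:
    """Label every pixel center as ceiling, floor, or one of the side walls.

    Pixels are classified exactly against the boundary lines of
    ``corners`` (no polygon clipping), which keeps the raster bit-exact
    and well defined even when corners fall outside the frame.  Ties on a
    boundary go to ceiling, then floor, then the wall.
    """
    frame = frame or corners.frame
    w, h = frame.width_px, frame.height_px
    cx, cy = frame.center
    xs = np.arange(w, dtype=float) - cx
    ys = np.arange(h, dtype=float) - cy
    X, Y = np.meshgrid(xs, ys)

    def evaluate(line: np.ndarray) -> np.ndarray:
        a, b, c = line
        return a * X + b * Y + c

    # Orient the separators so the annotated (middle) wall side is positive.
    inner = [p for p in (corners.p2, corners.p3, corners.p6, corners.p7) if not p.is_infinite]
    if len(inner) < 4:
        raise InvalidCornerSetError("wall corners at infinity")
    ref = np.mean([p.xy for p in inner], axis=0)

    def oriented(line: np.ndarray, positive_at: np.ndarray) -> np.ndarray:
        val = line @ np.append(positive_at, 1.0)
        if val == 0.0:
            raise InvalidCornerSetError("degenerate separator through the reference point")
        return line if val > 0 else -line

    left_sep = oriented(corners.lines["left_sep"], ref)
    right_sep = oriented(corners.lines["right_sep"], ref)
    in_left = evaluate(left_sep) < 0
    in_right = evaluate(right_sep) < 0
    in_middle = ~in_left & ~in_right

    def downward(line: np.ndarray) -> np.ndarray:
        if line[1] == 0.0:
            raise InvalidCornerSetError("vertical ceiling/floor boundary")
        return line if line[1] > 0 else -line

    labels = np.zeros((h, w), dtype=np.uint8)
    regions = (
        ("left", in_left, corners.lines["ceil_left"], corners.lines["floor_left"]),
        ("middle", in_middle, corners.lines["ceil_mid"], corners.lines["floor_mid"]),
        ("right", in_right, corners.lines["ceil_right"], corners.lines["floor_right"]),
    )
    wall_masks: list[tuple[str, np.ndarray]] = []
    for name, mask, ceil_line, floor_line in regions:
        above_ceil = evaluate(downward(ceil_line)) < 0
        below_floor = evaluate(downward(floor_line)) > 0
        if np.any(mask & above_ceil & below_floor):
            raise InvalidCornerSetError(f"ceiling and floor boundaries cross in the {name} region")
        labels[mask & above_ceil] = LABEL_CEILING
        labels[mask & below_floor & ~above_ceil] = LABEL_FLOOR
        wall_masks.append((name, mask & ~above_ceil & ~below_floor))

    legend = _base_legend()
    wall_slots: dict[int, str] = {}
    next_label = LABEL_FIRST_WALL
    for name, mask in wall_masks:  # already left-to-right
        if not np.any(mask):
            continue
        labels[mask] = next_label
        legend[next_label] = f"side wall {next_label - LABEL_FIRST_WALL + 1}"
        wall_slots[next_label] = name
        next_label += 1
    return LayoutSegmentation(labels, legend, wall_slots)


def wall_orientations(geom: VanishingGeometry, va: HomoPoint2D) -> tuple[float, float]:
    """Orientation angles theta_a = atan(|Oh Va|/h) and theta_o = atan(|Oh Vo|/h).

    These are the angles of the annotated and orthogonal walls measured
    from the direction whose vanishing point is Oh; they satisfy
    theta_a + theta_o = 90 degrees exactly (|Oh Va| |Oh Vo| = h^2).  At
    zero roll theta measures the wall's angle from the sagittal axis.
    """
    u_a = abs(geom.horizon_coordinate(va))
    if math.isinf(u_a):
        return 90.0, 0.0
    if u_a == 0.0:
        return 0.0, 90.0
    return math.degrees(math.atan(u_a / geom.h)), math.degrees(math.atan(geom.h / u_a))


@dataclass(frozen=True)
class AerialWallSpec:
    """A side wall in the observer-centered aerial view.

    ``orientation_deg`` is the angle of the wall *plane* relative to
    frontal (0 = facing the observer, 90 = parallel to the line of
    sight); the span is the wall's horizontal angular extent, negative
    azimuths to the observer's left.
    """

    orientation_deg: float
    phi_start_deg: float
    phi_end_deg: float
    label: int

    def __post_init__(self) -> None:
        if not self.phi_start_deg < self.phi_end_deg:
            raise ValueError("wall span must have positive width")


def _fold_to_quadrant(angle_deg: float) -> float:
    a = abs(angle_deg) % 180.0
    return min(a, 180.0 - a)


class _HorizonFrame:
    """Azimuth bookkeeping along the horizon of a calibrated camera.

    The camera center sits at distance h from the horizon line, with its
    foot at Oh; a point at signed coordinate u along H (from Oh) is seen
    at angle atan(u/h) from the Oh direction, so the azimuth relative to
    straight ahead is atan(u/h) - atan(u_s/h) with u_s the coordinate of
    Vs.  This pencil mapping is exact for any pitch and roll.
    """

    def __init__(self, camera: CameraModel) -> None:
        vs = camera.project_direction([0.0, 0.0, 1.0])
        vc = camera.project_direction([1.0, 0.0, 0.0])
        self.horizon = line_through(vs, vc)
        self.oh = foot_of_perpendicular(self.horizon)
        self.u_dir = line_direction(self.horizon)
        o_oh = float(np.hypot(*self.oh))
        self.h = math.hypot(camera.focal_length_px, o_oh)
        if vs.is_infinite:
            raise InvalidCornerSetError("vertical horizon")
        self.phi0_deg = math.degrees(math.atan(float((vs.xy - self.oh) @ self.u_dir) / self.h))

    def coordinate(self, p: HomoPoint2D) -> float:
        if p.is_infinite:
            return math.inf if float(p.v[:2] @ self.u_dir) > 0 else -math.inf
        return float((p.xy - self.oh) @ self.u_dir)

    def azimuth_deg(self, p: HomoPoint2D) -> float:
        u = self.coordinate(p)
        base = math.copysign(90.0, u) if math.isinf(u) else math.degrees(math.atan(u / self.h))
        return base - self.phi0_deg


def build_aerial_view(
    seg: LayoutSegmentation,
    corners: LayoutCorners,
    theta_a_deg: float,
    theta_o_deg: float,
    camera: CameraModel,
) -> list[AerialWallSpec]:
    """Aerial-view wall specs: plane orientation plus angular span per wall.

    Wall-plane orientations are computed from the azimuth of Va under the
    exact horizon pencil mapping (which reduces to 90 - theta_a at zero
    roll); spans run between the azimuths of the wall-wall corner lines,
    clipped to [-FOV/2, +FOV/2].  ``theta_a_deg``/``theta_o_deg`` are
    accepted for provenance and consistency checks by callers.
    """
    hf = _HorizonFrame(camera)
    half_fov = camera.fov_h_deg / 2.0

    phi_va = hf.azimuth_deg(corners.va)
    orient_mid = _fold_to_quadrant(phi_va - 90.0)
    orient_side = 90.0 - orient_mid

    u_left_pt = intersect(corners.lines["left_sep"], hf.horizon)
    u_right_pt = intersect(corners.lines["right_sep"], hf.horizon)
    phi_left = hf.azimuth_deg(u_left_pt)
    phi_right = hf.azimuth_deg(u_right_pt)
    if phi_right < phi_left:
        phi_left, phi_right = phi_right, phi_left

    spans = {
        "left": (-half_fov, phi_left, orient_side),
        "middle": (phi_left, phi_right, orient_mid),
        "right": (phi_right, half_fov, orient_side),
    }
    out: list[AerialWallSpec] = []
    for label in sorted(seg.wall_slots):
        slot = seg.wall_slots[label]
        start, end, orient = spans[slot]
        start, end = max(start, -half_fov), min(end, half_fov)
        if not start < end:
            warnings.warn(f"wall {label} has zero horizontal extent; dropped")
            continue
        out.append(AerialWallSpec(orient, start, end, label))
    return out


def pixel_error(seg: LayoutSegmentation, truth: LayoutSegmentation) -> float:
    """Percentage of pixels whose layout label differs from the ground truth."""
    if seg.labels.shape != truth.labels.shape:
        raise ValueError(
            f"segmentation shapes differ: {seg.labels.shape} vs {truth.labels.shape}"
        )
    return 100.0 * float(np.mean(seg.labels != truth.labels))
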