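"""Projective primitives for single-image geometry.

Pixel coordinates are 0-based pixel centers, x rightward, y downward.
The principal point is assumed to sit at the exact image center
((W-1)/2, (H-1)/2); *centered* coordinates are pixel coordinates with
that point subtracted, and all calibration math happens there.

Points are homogeneous 3-vectors so that vanishing points at infinity
(pure directions) are ordinary values rather than special cases.  Lines
are homogeneous 3-vectors ``(a, b, c)`` with incidence ``a x + b y + c = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Two lines closer in direction than this are treated as parallel and
#: intersected at infinity; sub-pixel noise on short annotated segments
#: otherwise produces absurd finite vanishing points.
DEFAULT_PARALLEL_TOL_DEG = 0.01


class DegenerateAnnotationError(ValueError):
    """Annotation carries no usable constraint (e.g. coincident lines)."""


class InconsistentAnnotationError(ValueError):
    """Annotation contradicts the orthogonality assumptions (f^2 <= 0 etc.)."""


@dataclass(frozen=True)
class ImageFrame:
    """Image dimensions plus the centered-coordinate convention."""

    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if self.width_px < 2 or self.height_px < 2:
            raise ValueError("image frame must be at least 2x2 pixels")

    @property
    def center(self) -> np.ndarray:
        """Principal point in 0-based pixel coordinates."""
        return np.array([(self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0])

    def to_centered(self, xy) -> np.ndarray:
        return np.asarray(xy, dtype=float) - self.center

    def from_centered(self, xy) -> np.ndarray:
        return np.asarray(xy, dtype=float) + self.center

    @property
    def bounds_centered(self) -> tuple[float, float, float, float]:
        """Outer pixel boundary (xmin, xmax, ymin, ymax) in centered coords."""
        w, h = self.width_px, self.height_px
        return (-w / 2.0, w / 2.0, -h / 2.0, h / 2.0)


class HomoPoint2D:
    """A 2D point in homogeneous coordinates; w == 0 means a point at infinity."""

    __slots__ = ("v",)

    def __init__(self, v) -> None:
        v = np.asarray(v, dtype=float)
        if v.shape != (3,):
            raise ValueError("homogeneous point needs 3 components")
        if not np.any(v):
            raise ValueError("all-zero homogeneous point")
        self.v = v

    @classmethod
    def finite(cls, x: float, y: float) -> "HomoPoint2D":
        return cls(np.array([x, y, 1.0]))

    @classmethod
    def at_infinity(cls, dx: float, dy: float) -> "HomoPoint2D":
        return cls(np.array([dx, dy, 0.0]))

    @property
    def is_infinite(self) -> bool:
        return self.v[2] == 0.0

    @property
    def xy(self) -> np.ndarray:
        """Inhomogeneous coordinates; raises for a point at infinity."""
        if self.is_infinite:
            raise ValueError("point at infinity has no affine coordinates")
        return self.v[:2] / self.v[2]

    @property
    def direction(self) -> np.ndarray:
        """Unit direction: toward the point from anywhere (infinite) or from O."""
        d = self.v[:2] if self.is_infinite else self.xy
        n = np.hypot(d[0], d[1])
        if n == 0.0:
            raise ValueError("no direction for the origin")
        return d / n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_infinite:
            return f"HomoPoint2D(infinity, dir={self.v[:2]})"
        return f"HomoPoint2D({self.xy[0]:.6g}, {self.xy[1]:.6g})"


@dataclass(frozen=True)
class LineSegment2D:
    """Segment between two pixel-coordinate endpoints (must be > 1 px apart)."""

    a: np.ndarray
    b: np.ndarray

    def __init__(self, a, b) -> None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != (2,) or b.shape != (2,):
            raise ValueError("segment endpoints must be 2-vectors")
        if np.hypot(*(b - a)) <= 1.0:
            raise ValueError("segment endpoints must be more than 1 px apart")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def direction(self) -> np.ndarray:
        d = self.b - self.a
        return d / np.hypot(d[0], d[1])

    @property
    def line(self) -> np.ndarray:
        """Homogeneous line through the two endpoints."""
        return np.cross(np.append(self.a, 1.0), np.append(self.b, 1.0))

    def translated(self, offset) -> "LineSegment2D":
        off = np.asarray(offset, dtype=float)
        return LineSegment2D(self.a + off, self.b + off)


def line_through(p: HomoPoint2D, q: HomoPoint2D) -> np.ndarray:
    """Homogeneous line through two homogeneous points."""
    l = np.cross(p.v, q.v)
    if not np.any(l):
        raise DegenerateAnnotationError("cannot draw a line through identical points")
    return l


def intersect(l1: np.ndarray, l2: np.ndarray) -> HomoPoint2D:
    """Intersection of two homogeneous lines."""
    p = np.cross(l1, l2)
    if not np.any(p):
        raise DegenerateAnnotationError("coincident lines have no unique intersection")
    # Snap a numerically negligible w to an exact point at infinity.
    if p[2] != 0.0 and abs(p[2]) < 1e-14 * np.hypot(p[0], p[1]):
        p = np.array([p[0], p[1], 0.0])
    return HomoPoint2D(p)


def intersect_lines(
    seg_a: LineSegment2D,
    seg_b: LineSegment2D,
    tol_parallel_deg: float = DEFAULT_PARALLEL_TOL_DEG,
) -> HomoPoint2D:
    """Intersect the infinite lines through two segments.

    Lines within ``tol_parallel_deg`` of parallel are intersected at
    infinity along their (shared) direction; coincident lines raise
    :class:`DegenerateAnnotationError`.
    """
    da, db = seg_a.direction, seg_b.direction
    sin_angle = abs(da[0] * db[1] - da[1] * db[0])
    if sin_angle < math.sin(math.radians(tol_parallel_deg)):
        # Parallel within tolerance: coincident if seg_b's endpoint sits on
        # seg_a's infinite line (perpendicular distance below 1e-6 px).
        la = seg_a.line
        dist = abs(la @ np.append(seg_b.a, 1.0)) / np.hypot(la[0], la[1])
        if dist < 1e-6:
            raise DegenerateAnnotationError("segments lie on the same line")
        return HomoPoint2D.at_infinity(*da)
    return intersect(seg_a.line, seg_b.line)


def foot_of_perpendicular(line: np.ndarray, point=(0.0, 0.0)) -> np.ndarray:
    """Foot of the perpendicular from ``point`` onto a homogeneous line."""
    a, b, c = line
    n2 = a * a + b * b
    if n2 == 0.0:
        raise ValueError("line at infinity has no perpendicular foot")
    x0, y0 = point
    t = (a * x0 + b * y0 + c) / n2
    return np.array([x0 - a * t, y0 - b * t])


def line_direction(line: np.ndarray) -> np.ndarray:
    """Unit direction along a line, oriented with positive x (or positive y)."""
    a, b, _ = line
    d = np.array([b, -a]) / math.hypot(a, b)
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return d


def signed_coordinate(p: HomoPoint2D, origin: np.ndarray, direction: np.ndarray) -> float:
    """Signed position of a collinear point along ``direction`` from ``origin``.

    Returns ``+/-inf`` for a point at infinity (sign from its direction).
    """
    if p.is_infinite:
        s = float(p.v[:2] @ direction)
        return math.inf if s > 0 else -math.inf if s < 0 else math.nan
    return float((p.xy - origin) @ direction)


def clip_segment_to_box(
    p_from: np.ndarray, direction: np.ndarray, bounds: tuple[float, float, float, float]
) -> np.ndarray | None:
    """March from ``p_from`` along ``direction`` to the box boundary.

    Returns the exit point of the ray from ``p_from`` (which may lie outside
    the box) through the box, or None when the ray misses the box entirely.
    """
    xmin, xmax, ymin, ymax = bounds
    t_lo, t_hi = 0.0, math.inf
    p = p_from
    d = direction
    for lo, hi, pc, dc in ((xmin, xmax, p[0], d[0]), (ymin, ymax, p[1], d[1])):
        if dc == 0.0:
            if pc < lo or pc > hi:
                return None
            continue
        t1, t2 = (lo - pc) / dc, (hi - pc) / dc
        if t1 > t2:
            t1, t2 = t2, t1
        t_lo, t_hi = max(t_lo, t1), min(t_hi, t2)
    if t_hi < t_lo:
        return None
    return p + t_hi * d
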