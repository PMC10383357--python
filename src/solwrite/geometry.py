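"""Planar geometric primitives for shape tracing.

All coordinates are image-style pixels: origin at the top-left corner,
x increasing rightward, y increasing downward.  "Bottom" therefore means
larger y throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

__all__ = [
    "Point2D",
    "Segment",
    "DegenerateSegmentError",
    "segment_angle",
    "projection_parameter",
    "point_segment_distance",
    "signed_line_distance",
    "nearest_segment",
    "is_legal_draw_point",
]


class DegenerateSegmentError(ValueError):
    """Raised when an operation receives a zero-length segment."""


@dataclass(frozen=True)
class Point2D:
    """A point in pixel coordinates (y grows downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Segment:
    """A directed straight line segment between two pixel points.

    ``angle`` is orientation-free in [0, pi): a segment and its reverse
    report the same angle.  Angle is used instead of slope so vertical
    lines need no special casing.
    """

    p0: Point2D
    p1: Point2D

    @property
    def dx(self) -> float:
        return self.p1.x - self.p0.x

    @property
    def dy(self) -> float:
        return self.p1.y - self.p0.y

    @property
    def length(self) -> float:
        return math.hypot(self.dx, self.dy)

    @property
    def angle(self) -> float:
        return segment_angle(self)

    @property
    def midpoint(self) -> Point2D:
        return Point2D((self.p0.x + self.p1.x) / 2.0, (self.p0.y + self.p1.y) / 2.0)

    def reversed(self) -> "Segment":
        return Segment(self.p1, self.p0)

    def point_at(self, t: float) -> Point2D:
        return Point2D(self.p0.x + t * self.dx, self.p0.y + t * self.dy)


def _require_nondegenerate(seg: Segment) -> None:
    if seg.length <= 0.0:
        raise DegenerateSegmentError(f"zero-length segment at {seg.p0}")


def segment_angle(seg: Segment) -> float:
    """Orientation-free angle of a segment, in radians in [0, pi).

    Reversing the segment's endpoints yields the same angle.  The y-down
    image convention does not affect the magnitude of the angle.
    """
    _require_nondegenerate(seg)
    a = math.atan2(seg.dy, seg.dx) % math.pi
    # atan2 of an exactly-reversed horizontal segment gives pi; fold it.
    if a >= math.pi:
        a -= math.pi
    return a


def angle_difference(a: float, b: float) -> float:
    """Distance between two orientation-free angles on the half-circle."""
    d = abs(a - b) % math.pi
    return min(d, math.pi - d)


def projection_parameter(p: Point2D, seg: Segment) -> float:
    """Scalar position of p's perpendicular foot along seg's carrier line.

    t = 0 at ``p0``, t = 1 at ``p1``, linear along the line; t in [0, 1]
    iff the foot of the perpendicular lies between the endpoints.
    """
    _require_nondegenerate(seg)
    vx, vy = seg.dx, seg.dy
    wx, wy = p.x - seg.p0.x, p.y - seg.p0.y
    return (wx * vx + wy * vy) / (vx * vx + vy * vy)


def point_segment_distance(p: Point2D, seg: Segment) -> float:
    """Euclidean distance from p to the closest point of the clamped segment."""
    t = projection_parameter(p, seg)
    t = min(1.0, max(0.0, t))
    return p.distance_to(seg.point_at(t))


def signed_line_distance(p: Point2D, seg: Segment) -> float:
    """Signed perpendicular distance from p to seg's carrier line.

    Positive on the left of the p0->p1 direction (in y-down screen
    coordinates); mirroring p across the line flips the sign.  Only the
    relative sign matters for the mean-deviation statistic.
    """
    _require_nondegenerate(seg)
    cross = seg.dx * (p.y - seg.p0.y) - seg.dy * (p.x - seg.p0.x)
    return -cross / seg.length


def nearest_segment(p: Point2D, segments: Sequence[Segment]) -> Tuple[int, float]:
    """Index and distance of the segment closest to p; ties go to the lowest index."""
    if not segments:
        raise ValueError("nearest_segment requires at least one segment")
    best_i, best_d = 0, point_segment_distance(p, segments[0])
    for i, seg in enumerate(segments[1:], start=1):
        d = point_segment_distance(p, seg)
        if d < best_d:
            best_i, best_d = i, d
    return best_i, best_d


def is_legal_draw_point(
    p: Point2D, shape: "Shape", radius: float
) -> Tuple[bool, int, float]:
    """Decide whether a drawing point collides with the shape.

    A draw point is legal iff its minimum clamped distance to any shape
    segment is at most the drawing radius.  Returns ``(legal, segment
    index, signed carrier-line deviation)``; the deviation of the matched
    segment feeds the spasticity log regardless of legality.
    """
    idx, dist = nearest_segment(p, shape.segments)
    deviation = signed_line_distance(p, shape.segments[idx])
    return dist <= radius, idx, deviation
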