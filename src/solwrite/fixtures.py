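"""Synthetic fixtures: rendered shape images and simulated hand streams.

Everything needed to exercise the system without a camera.  The
renderer rasterizes a known stroke list into a compliant 512x512
black-on-white image and also returns the analytic ground-truth
:class:`~solwrite.detection.Shape`, so detection output can be checked
against exact geometry.  The simulator emits 21-landmark streams whose
index fingertip follows the shape path at a chosen speed with
perpendicular Gaussian tremor, optionally interrupted by scripted
failure events (pinch release, an off-shape jump, dropped hand frames).

The noise model is perpendicular-only: tremor along the path changes
speed, not deviation, so the spasticity estimator has the closed-form
expectation E|N(0, sigma)| = sigma * sqrt(2/pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image, ImageDraw

from .detection import (
    WORKING_SIZE,
    DetectionParams,
    Shape,
    ShapeImage,
    assign_endpoints,
    classify_topology,
    order_path,
)
from .geometry import Point2D, Segment
from .hand import INDEX_TIP, MIDDLE_TIP, N_LANDMARKS, THUMB_TIP, LandmarkFrame

__all__ = [
    "StrokeSpec",
    "TrajectorySpec",
    "BUILTIN_SHAPES",
    "builtin_stroke_spec",
    "ground_truth_shape",
    "render_shape_image",
    "simulate_trajectory",
    "half_trace",
    "HAND_TEMPLATE",
]


@dataclass(frozen=True)
class StrokeSpec:
    """An ordered list of straight strokes in 512x512 shape space."""

    strokes: Tuple[Tuple[Tuple[float, float], Tuple[float, float]], ...]
    stroke_width: int = 4
    name: str = ""

    def __post_init__(self) -> None:
        if not self.strokes:
            raise ValueError("StrokeSpec requires at least one stroke")
        for (x0, y0), (x1, y1) in self.strokes:
            for v in (x0, y0, x1, y1):
                if not 0 <= v < WORKING_SIZE:
                    raise ValueError(
                        f"stroke endpoint ({v}) outside the {WORKING_SIZE}px canvas"
                    )

    def segments(self) -> List[Segment]:
        return [
            Segment(Point2D(*p0), Point2D(*p1)) for p0, p1 in self.strokes
        ]


# Built-in glyphs.  The letter M is drawn with four straight lines, the
# rectangle and triangle are closed loops, and the Greek capital Pi has
# three strokes (two legs and the top bar).
BUILTIN_SHAPES: Dict[str, StrokeSpec] = {
    "M": StrokeSpec(
        strokes=(
            ((110.0, 430.0), (110.0, 82.0)),
            ((110.0, 82.0), (256.0, 300.0)),
            ((256.0, 300.0), (402.0, 82.0)),
            ((402.0, 82.0), (402.0, 430.0)),
        ),
        name="M",
    ),
    "rectangle": StrokeSpec(
        strokes=(
            ((120.0, 140.0), (392.0, 140.0)),
            ((392.0, 140.0), (392.0, 372.0)),
            ((392.0, 372.0), (120.0, 372.0)),
            ((120.0, 372.0), (120.0, 140.0)),
        ),
        name="rectangle",
    ),
    "Pi": StrokeSpec(
        strokes=(
            ((140.0, 420.0), (140.0, 120.0)),
            ((140.0, 120.0), (372.0, 120.0)),
            ((372.0, 120.0), (372.0, 420.0)),
        ),
        name="Pi",
    ),
    "triangle": StrokeSpec(
        strokes=(
            ((256.0, 110.0), (110.0, 400.0)),
            ((110.0, 400.0), (402.0, 400.0)),
            ((402.0, 400.0), (256.0, 110.0)),
        ),
        name="triangle",
    ),
}


def builtin_stroke_spec(name: str) -> StrokeSpec:
    try:
        return BUILTIN_SHAPES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; built-ins: {sorted(BUILTIN_SHAPES)}"
        ) from None


def ground_truth_shape(spec: StrokeSpec) -> Shape:
    """Analytic Shape for a stroke spec (exact segments, no raster step).

    Topology, endpoints and path ordering are derived from the exact
    stroke geometry with the same junction rules the detector uses, so
    the ground truth and a detection result are directly comparable.
    """
    params = DetectionParams(junction_tol=1e-6)
    segs = spec.segments()
    topology = classify_topology(segs, params)
    start, end = assign_endpoints(segs, topology, params)
    ordered = order_path(segs, topology, start, params)
    return Shape(
        segments=tuple(ordered),
        topology=topology,
        start=start,
        end=end,
        perimeter=sum(s.length for s in ordered),
        name=spec.name,
    )


def render_shape_image(spec: StrokeSpec) -> Tuple[ShapeImage, Shape]:
    """Rasterize the strokes black-on-white and return the analytic truth."""
    im = Image.new("L", (WORKING_SIZE, WORKING_SIZE), 255)
    draw = ImageDraw.Draw(im)
    w = spec.stroke_width
    for (x0, y0), (x1, y1) in spec.strokes:
        draw.line([(x0, y0), (x1, y1)], fill=0, width=w)
        # round the joints so strokes connect cleanly
        r = w / 2.0
        for x, y in ((x0, y0), (x1, y1)):
            draw.ellipse([x - r, y - r, x + r, y + r], fill=0)
    return ShapeImage(np.asarray(im, dtype=np.uint8)), ground_truth_shape(spec)


# ---------------------------------------------------------------------------
# trajectory simulation

# Rigid 21-landmark template: pixel offsets of each landmark relative to
# the index fingertip, anatomically plausible for a right hand in tripod
# pose.  Only landmarks 4 (thumb), 8 (index) and 12 (middle) influence
# the engine; the rest give downstream consumers a complete hand.
HAND_TEMPLATE: Tuple[Tuple[float, float], ...] = (
    (10.0, 160.0),   # 0 wrist
    (-28.0, 130.0),  # 1 thumb CMC
    (-30.0, 95.0),   # 2 thumb MCP
    (-22.0, 55.0),   # 3 thumb IP
    (-10.0, 18.0),   # 4 thumb tip
    (-8.0, 110.0),   # 5 index MCP
    (-5.0, 70.0),    # 6 index PIP
    (-2.0, 35.0),    # 7 index DIP
    (0.0, 0.0),      # 8 index tip (the drawing fingertip)
    (18.0, 112.0),   # 9 middle MCP
    (17.0, 72.0),    # 10 middle PIP
    (14.0, 40.0),    # 11 middle DIP
    (12.0, 14.0),    # 12 middle tip
    (42.0, 118.0),   # 13 ring MCP
    (40.0, 82.0),    # 14 ring PIP
    (38.0, 58.0),    # 15 ring DIP
    (36.0, 42.0),    # 16 ring tip
    (64.0, 128.0),   # 17 pinky MCP
    (62.0, 98.0),    # 18 pinky PIP
    (60.0, 78.0),    # 19 pinky DIP
    (58.0, 66.0),    # 20 pinky tip
)

# Displacement applied to the thumb and middle fingertips during a
# release_pinch event; large enough to break any plausible threshold.
_RELEASE_OFFSET = 200.0
# One-frame index-fingertip displacement of a jump_off_shape event:
# five times the widest drawing radius, so it is out of bounds at any
# configured radius.
_JUMP_OFFSET = 200.0
# Frames suppressed by a drop_hand event span this many seconds.
_DROP_SPAN = 0.5


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of a simulated tracing session.

    speed is the fingertip's along-path speed in px/s; tremor_sigma the
    standard deviation (px) of the perpendicular Gaussian noise; events
    is a sequence of ``(time_s, kind)`` with kind one of
    ``release_pinch``, ``jump_off_shape``, ``drop_hand``.
    """

    shape: StrokeSpec
    speed: float = 100.0
    tremor_sigma: float = 0.0
    frame_rate: float = 60.0
    events: Tuple[Tuple[float, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.tremor_sigma < 0:
            raise ValueError("tremor_sigma must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for _, kind in self.events:
            if kind not in ("release_pinch", "jump_off_shape", "drop_hand"):
                raise ValueError(f"unknown event kind {kind!r}")


class _PathWalker:
    """Maps arc length s along the ordered shape path to point + direction."""

    def __init__(self, shape: Shape):
        self.segments = shape.segments
        self.cum = [0.0]
        for s in self.segments:
            self.cum.append(self.cum[-1] + s.length)
        self.total = self.cum[-1]

    def at(self, s: float) -> Tuple[Point2D, Tuple[float, float]]:
        s = min(max(s, 0.0), self.total)
        for i, seg in enumerate(self.segments):
            if s <= self.cum[i + 1] or i == len(self.segments) - 1:
                local = s - self.cum[i]
                t = local / seg.length
                ux, uy = seg.dx / seg.length, seg.dy / seg.length
                return seg.point_at(t), (ux, uy)
        raise AssertionError("unreachable")


def _frame_at(
    tip: Point2D,
    t: float,
    release: bool,
) -> LandmarkFrame:
    pts = []
    for i, (ox, oy) in enumerate(HAND_TEMPLATE):
        x, y = tip.x + ox, tip.y + oy
        if release and i in (THUMB_TIP, MIDDLE_TIP):
            x += _RELEASE_OFFSET
        pts.append(Point2D(x, y))
    return LandmarkFrame(landmarks=tuple(pts), timestamp=t)


def simulate_trajectory(
    spec: TrajectorySpec,
    stop_fraction: float = 1.0,
    idle_until: Optional[float] = None,
) -> List[LandmarkFrame]:
    """Simulate a tracing session as a landmark stream.

    The index fingertip starts on the shape's start point, advances
    along the path at ``spec.speed`` with perpendicular Gaussian tremor,
    and stops after covering ``stop_fraction`` of the path.  If
    ``idle_until`` is given, the hand then holds position (still
    pinched, still trembling) until that time; otherwise the stream ends
    about a second after the fingertip reaches its stopping point.

    Events: ``release_pinch`` moves the thumb and middle fingertips away
    from the index fingertip from its event time on; ``jump_off_shape``
    displaces the index fingertip by 200 px perpendicular to the path
    for exactly one frame; ``drop_hand`` suppresses half a second of
    frames (a gap longer than the engine's loss tolerance).

    Same seed, same spec => byte-identical stream.
    """
    if not 0.0 < stop_fraction <= 1.0:
        raise ValueError("stop_fraction must be in (0, 1]")
    shape = ground_truth_shape(spec.shape)
    walker = _PathWalker(shape)
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate
    s_stop = stop_fraction * walker.total
    t_reach = s_stop / spec.speed
    t_end = idle_until if idle_until is not None else t_reach + 1.0

    jumps = sorted(t for t, k in spec.events if k == "jump_off_shape")
    releases = sorted(t for t, k in spec.events if k == "release_pinch")
    drops = [(t, t + _DROP_SPAN) for t, k in spec.events if k == "drop_hand"]

    frames: List[LandmarkFrame] = []
    k = 0
    jumped = set()
    while True:
        t = k * dt
        if t > t_end:
            break
        k += 1
        if any(a < t <= b for a, b in drops):
            continue  # dropped detection: no frame emitted
        s = min(spec.speed * t, s_stop)
        pos, (ux, uy) = walker.at(s)
        nx, ny = -uy, ux  # unit normal to the path direction
        offset = rng.normal(0.0, spec.tremor_sigma) if spec.tremor_sigma > 0 else 0.0
        tip = Point2D(pos.x + offset * nx, pos.y + offset * ny)
        ji = next((j for j in jumps if j not in jumped and t >= j), None)
        if ji is not None:
            jumped.add(ji)
            # jump off the shape: of the two perpendicular directions,
            # take the one landing farther from every stroke
            from .geometry import nearest_segment

            candidates = [
                Point2D(tip.x + s * _JUMP_OFFSET * nx, tip.y + s * _JUMP_OFFSET * ny)
                for s in (+1.0, -1.0)
            ]
            tip = max(
                candidates, key=lambda p: nearest_segment(p, shape.segments)[1]
            )
        release = any(t >= r for r in releases)
        frames.append(_frame_at(tip, t, release))
    return frames


def half_trace(spec: TrajectorySpec, fraction: float) -> List[LandmarkFrame]:
    """Trace the given fraction of the path, then idle in place until 60 s.

    ``fraction`` = 1.0 reduces to a plain full trace (no idling).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return simulate_trajectory(spec)
    return simulate_trajectory(spec, stop_fraction=fraction, idle_until=61.0)
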