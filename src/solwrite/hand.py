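"""21-landmark hand frames, tripod-pinch detection and the drawing point.

Landmark indexing follows the MediaPipe hand convention: 0 = wrist,
4 = thumb tip, 8 = index finger tip, 12 = middle finger tip, 20 = pinky
tip.  The landmark SOURCE is abstracted behind a provider: file replay
(JSON Lines), the built-in simulator, or an optional live camera
adapter; the core engine only ever sees :class:`LandmarkFrame` records.

Stream format (JSON Lines, one frame per line)::

    {"t": <seconds>, "lm": [[x, y], ... 21 pairs ...]}

Coordinates are display pixels, already in display orientation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence

from .geometry import Point2D

__all__ = [
    "N_LANDMARKS",
    "WRIST",
    "THUMB_TIP",
    "INDEX_TIP",
    "MIDDLE_TIP",
    "LandmarkFrame",
    "DrawPoint",
    "RADIUS_MIN",
    "RADIUS_MAX",
    "fingertip_distance",
    "is_tripod_pinch",
    "drawing_point",
    "HandSelector",
    "read_stream",
    "write_stream",
]

N_LANDMARKS = 21
WRIST = 0
THUMB_TIP = 4
INDEX_TIP = 8
MIDDLE_TIP = 12

# drawing-radius bounds, pixels: 20 is the strictest tolerance, 40 the
# most permissive (difficulty adjustment for the patient)
RADIUS_MIN = 20.0
RADIUS_MAX = 40.0


@dataclass(frozen=True)
class LandmarkFrame:
    """One timestamped set of 21 hand keypoints in display pixels."""

    landmarks: tuple  # 21 Point2D
    timestamp: float  # seconds, strictly increasing within a stream

    def __post_init__(self) -> None:
        if len(self.landmarks) != N_LANDMARKS:
            raise ValueError(
                f"expected {N_LANDMARKS} landmarks, got {len(self.landmarks)}"
            )

    def __getitem__(self, idx: int) -> Point2D:
        return self.landmarks[idx]

    def to_json(self) -> str:
        return json.dumps(
            {"t": self.timestamp, "lm": [[p.x, p.y] for p in self.landmarks]}
        )

    @classmethod
    def from_json(cls, line: str) -> "LandmarkFrame":
        d = json.loads(line)
        return cls(
            landmarks=tuple(Point2D(float(x), float(y)) for x, y in d["lm"]),
            timestamp=float(d["t"]),
        )


@dataclass(frozen=True)
class DrawPoint:
    """The tracing disc: centered on the index fingertip, radius = tolerance."""

    center: Point2D
    radius: float

    def __post_init__(self) -> None:
        if not RADIUS_MIN <= self.radius <= RADIUS_MAX:
            raise ValueError(
                f"drawing radius {self.radius} outside [{RADIUS_MIN:g}, {RADIUS_MAX:g}] px"
            )


def fingertip_distance(frame: LandmarkFrame, a: int, b: int) -> float:
    """Euclidean (Pythagorean) distance between two landmarks, pixels."""
    if not (0 <= a < N_LANDMARKS and 0 <= b < N_LANDMARKS):
        raise IndexError(f"landmark index out of range: {a}, {b}")
    return frame[a].distance_to(frame[b])


def is_tripod_pinch(frame: LandmarkFrame, threshold: float) -> bool:
    """True iff thumb, index and middle fingertips are pinched together.

    Both the index-to-thumb and middle-to-thumb distances must be
    strictly below the threshold.  The threshold is calibrated for a
    hand about 50 cm from a 1280x720 camera (default 60 px).
    """
    return (
        fingertip_distance(frame, THUMB_TIP, INDEX_TIP) < threshold
        and fingertip_distance(frame, THUMB_TIP, MIDDLE_TIP) < threshold
    )


def drawing_point(frame: LandmarkFrame, radius: float) -> DrawPoint:
    """The drawing disc for this frame: index fingertip + configured radius."""
    return DrawPoint(center=frame[INDEX_TIP], radius=radius)


class HandSelector:
    """Sticky first-hand selection when several hands are visible.

    The hand first seen in the stream is the patient's working hand;
    later detections are matched to it by wrist-landmark continuity and
    all other hands are ignored.  When no candidate is near the last
    tracked wrist the hand is reported lost (``None``) until one
    reappears nearby.  State is per session; call :meth:`reset` between
    sessions.
    """

    def __init__(self, continuity_radius: float = 150.0):
        self.continuity_radius = continuity_radius
        self._last_wrist: Optional[Point2D] = None

    def reset(self) -> None:
        self._last_wrist = None

    def select(
        self, detections: Sequence[LandmarkFrame]
    ) -> Optional[LandmarkFrame]:
        if not detections:
            return None
        if self._last_wrist is None:
            chosen = detections[0]
        else:
            near = [
                f
                for f in detections
                if f[WRIST].distance_to(self._last_wrist) <= self.continuity_radius
            ]
            if not near:
                return None  # tracked hand lost; ignore strangers
            chosen = min(
                near, key=lambda f: f[WRIST].distance_to(self._last_wrist)
            )
        self._last_wrist = chosen[WRIST]
        return chosen


def read_stream(path) -> Iterator[LandmarkFrame]:
    """Iterate LandmarkFrames from a JSONL file; errors carry line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield LandmarkFrame.from_json(line)
            except (ValueError, KeyError, TypeError) as e:
                raise ValueError(f"{path}:{lineno}: malformed frame: {e}") from e


def write_stream(frames: Iterable[LandmarkFrame], path) -> int:
    """Write frames as JSONL; returns the number of frames written."""
    n = 0
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f.to_json() + "\n")
            n += 1
    return n
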