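"""Per-frame session state machine for the virtual tracing test.

The automaton: the session idles until the patient, holding a tripod
pinch, places the index fingertip on the start dot (arming).  While
tracing, every frame is checked in order for timeout, grip/hand loss,
and drawing-point legality; a legal frame logs its signed deviation and
advances the drawn length.  The test completes when the drawn length
closely matches the shape's perimeter and the index fingertip is within
the end dot's vicinity.  Terminal phases are absorbing, so replaying a
recorded stream is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, List, Optional, Tuple

from .detection import Shape
from .geometry import Point2D, is_legal_draw_point
from .hand import (
    INDEX_TIP,
    RADIUS_MAX,
    RADIUS_MIN,
    LandmarkFrame,
    drawing_point,
    is_tripod_pinch,
)

__all__ = [
    "Phase",
    "FailReason",
    "Outcome",
    "SessionConfig",
    "SessionState",
    "SessionResult",
    "StreamError",
    "try_arm",
    "step",
    "completion_check",
    "fraction_traced",
    "finalize",
    "run_session",
    "compute_shape_transform",
]


class Phase(str, Enum):
    IDLE = "IDLE"
    TRACING = "TRACING"
    COMPLETED = "COMPLETED"
    FAILED = "FAILED"
    TIMED_OUT = "TIMED_OUT"


TERMINAL_PHASES = {Phase.COMPLETED, Phase.FAILED, Phase.TIMED_OUT}


class FailReason(str, Enum):
    NONE = "none"
    OUT_OF_BOUNDS = "out_of_bounds"
    GRIP_LOST = "grip_lost"
    HAND_LOST = "hand_lost"


class Outcome(str, Enum):
    COMPLETED = "completed"
    PARTIAL = "partial"
    FAILED = "failed"


class StreamError(ValueError):
    """The landmark stream violates its contract (e.g. non-monotone time)."""


@dataclass(frozen=True)
class SessionConfig:
    """Session parameters.

    radius: drawing-disc radius in pixels, within [20, 40]; smaller is
        stricter.
    pinch_threshold: fingertip distance in pixels below which the tripod
        pinch is considered held (default 60 px at ~50 cm from a 720p
        camera).
    time_limit: seconds allowed for the trace (default 60 s, the
        standard per-task limit of the hand function test).
    length_match_fraction: fraction of the perimeter that counts as
        "closely matching" the shape's total length (default 0.9).
    end_vicinity: pixel distance to the end dot that counts as reaching
        it; defaults to the drawing radius.
    hand_loss_tolerance: gap in seconds between consecutive frames
        tolerated before the hand is declared lost (default 0.25 s, so a
        few dropped detections do not fail the test).
    """

    radius: float = RADIUS_MIN
    pinch_threshold: float = 60.0
    time_limit: float = 60.0
    length_match_fraction: float = 0.9
    end_vicinity: Optional[float] = None
    hand_loss_tolerance: float = 0.25

    def __post_init__(self) -> None:
        if not RADIUS_MIN <= self.radius <= RADIUS_MAX:
            raise ValueError(
                f"drawing radius {self.radius} outside "
                f"[{RADIUS_MIN:g}, {RADIUS_MAX:g}] px"
            )
        for name in ("pinch_threshold", "time_limit", "length_match_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def end_radius(self) -> float:
        return self.radius if self.end_vicinity is None else self.end_vicinity


@dataclass(frozen=True)
class SessionState:
    """Immutable snapshot of the automaton after processing a frame."""

    phase: Phase = Phase.IDLE
    start_time: Optional[float] = None
    last_time: Optional[float] = None
    drawn_length: float = 0.0
    last_draw_point: Optional[Point2D] = None  # projection onto the shape path
    deviations: Tuple[float, ...] = ()
    fail_reason: FailReason = FailReason.NONE

    @property
    def terminal(self) -> bool:
        return self.phase in TERMINAL_PHASES

    def elapsed_at(self, t: float) -> float:
        return 0.0 if self.start_time is None else t - self.start_time


@dataclass(frozen=True)
class SessionResult:
    """Final record of a session, input to scoring."""

    outcome: Outcome
    elapsed: float  # seconds from arming to the terminal frame
    fraction_traced: float  # in [0, 1]
    deviations: Tuple[float, ...]
    fail_reason: FailReason = FailReason.NONE


def try_arm(state: SessionState, frame: LandmarkFrame, cfg: SessionConfig,
            shape: Shape) -> SessionState:
    """Arm the session: pinched grip with the index tip on the start dot.

    Stays IDLE otherwise; stamps ``start_time`` on the transition.
    """
    if state.phase is not Phase.IDLE:
        raise ValueError(f"try_arm requires IDLE, got {state.phase}")
    if (
        is_tripod_pinch(frame, cfg.pinch_threshold)
        and frame[INDEX_TIP].distance_to(shape.start) <= cfg.end_radius
    ):
        return replace(
            state,
            phase=Phase.TRACING,
            start_time=frame.timestamp,
            last_time=frame.timestamp,
            last_draw_point=shape.start,
        )
    return replace(state, last_time=frame.timestamp)


def completion_check(
    state: SessionState, frame: LandmarkFrame, cfg: SessionConfig, shape: Shape
) -> bool:
    """True iff the trace is long enough and the fingertip is at the end dot.

    For closed shapes end == start; the length condition is the safety
    step that prevents instant completion at the shared start/end dot.
    """
    return (
        state.drawn_length >= cfg.length_match_fraction * shape.perimeter
        and frame[INDEX_TIP].distance_to(shape.end) <= cfg.end_radius
    )


def step(
    state: SessionState, frame: LandmarkFrame, cfg: SessionConfig, shape: Shape
) -> SessionState:
    """Process one frame while TRACING.

    Checks run in order: timeout, hand/grip loss, drawing-point
    legality; a legal frame appends its signed deviation and advances
    ``drawn_length`` by the step between successive projections onto the
    matched segment (capped at 3x radius so a dropped-frame jump cannot
    teleport the trace forward), then tests for completion.
    """
    if state.phase is not Phase.TRACING:
        raise ValueError(f"step requires TRACING, got {state.phase}")
    t = frame.timestamp
    if state.last_time is not None and t <= state.last_time:
        raise StreamError(
            f"non-monotone timestamp: {t} after {state.last_time}"
        )
    if state.elapsed_at(t) > cfg.time_limit:
        return replace(state, phase=Phase.TIMED_OUT, last_time=t)
    if state.last_time is not None and t - state.last_time > cfg.hand_loss_tolerance:
        return replace(
            state, phase=Phase.FAILED, fail_reason=FailReason.HAND_LOST, last_time=t
        )
    if not is_tripod_pinch(frame, cfg.pinch_threshold):
        return replace(
            state, phase=Phase.FAILED, fail_reason=FailReason.GRIP_LOST, last_time=t
        )
    dp = drawing_point(frame, cfg.radius)
    legal, seg_idx, deviation = is_legal_draw_point(dp.center, shape, dp.radius)
    if not legal:
        return replace(
            state,
            phase=Phase.FAILED,
            fail_reason=FailReason.OUT_OF_BOUNDS,
            last_time=t,
        )
    # advance along the matched segment, not the raw fingertip path
    seg = shape.segments[seg_idx]
    from .geometry import projection_parameter

    tt = min(1.0, max(0.0, projection_parameter(dp.center, seg)))
    proj = seg.point_at(tt)
    advance = 0.0
    if state.last_draw_point is not None:
        advance = min(proj.distance_to(state.last_draw_point), 3.0 * cfg.radius)
    new_state = replace(
        state,
        drawn_length=state.drawn_length + advance,
        last_draw_point=proj,
        deviations=state.deviations + (deviation,),
        last_time=t,
    )
    if completion_check(new_state, frame, cfg, shape):
        return replace(new_state, phase=Phase.COMPLETED)
    return new_state


def fraction_traced(state: SessionState, shape: Shape) -> float:
    """Fraction of the shape's perimeter covered, capped at 1."""
    if shape.perimeter <= 0:
        raise ValueError("shape has zero perimeter")
    return min(1.0, state.drawn_length / shape.perimeter)


def finalize(state: SessionState, shape: Shape) -> SessionResult:
    """Map a terminal state to a SessionResult (outcome, elapsed, fraction)."""
    if not state.terminal:
        raise ValueError(f"finalize requires a terminal phase, got {state.phase}")
    outcome = {
        Phase.COMPLETED: Outcome.COMPLETED,
        Phase.TIMED_OUT: Outcome.PARTIAL,
        Phase.FAILED: Outcome.FAILED,
    }[state.phase]
    elapsed = 0.0
    if state.start_time is not None and state.last_time is not None:
        elapsed = state.last_time - state.start_time
    if state.phase is Phase.TIMED_OUT:
        elapsed = min(elapsed, 60.0)
    return SessionResult(
        outcome=outcome,
        elapsed=elapsed,
        fraction_traced=fraction_traced(state, shape),
        deviations=state.deviations,
        fail_reason=state.fail_reason,
    )


def run_session(
    frames: Iterable[LandmarkFrame],
    shape: Shape,
    cfg: SessionConfig,
    audit_log: Optional[List[dict]] = None,
) -> SessionResult:
    """Replay a landmark stream through the automaton.

    A stream that ends while still TRACING counts as a hand loss; a
    stream that never arms yields a failed result with nothing traced.
    When ``audit_log`` is given, one record per processed frame is
    appended (phase, draw point, deviation) for audit and re-replay.
    """
    state = SessionState()
    for frame in frames:
        if state.phase is Phase.IDLE:
            state = try_arm(state, frame, cfg, shape)
        elif state.phase is Phase.TRACING:
            state = step(state, frame, cfg, shape)
        if audit_log is not None:
            dev = state.deviations[-1] if state.deviations else None
            audit_log.append(
                {
                    "t": frame.timestamp,
                    "phase": state.phase.value,
                    "draw": [frame[INDEX_TIP].x, frame[INDEX_TIP].y],
                    "deviation": dev,
                    "drawn_length": state.drawn_length,
                }
            )
        if state.terminal:
            break
    if not state.terminal:
        if state.phase is Phase.TRACING:
            state = replace(
                state, phase=Phase.FAILED, fail_reason=FailReason.HAND_LOST
            )
        else:  # never armed
            state = replace(state, phase=Phase.FAILED)
    return finalize(state, shape)


def compute_shape_transform(
    display_w: int, display_h: int, shape_size: int = 512, fill: float = 0.9
) -> Tuple[float, Point2D]:
    """Uniform scale + centering offset mapping shape space to display space.

    The 512x512 shape square maps to a centered square of height
    ``fill`` x the display height, preserving aspect ratio.
    """
    scale = fill * display_h / shape_size
    side = scale * shape_size
    offset = Point2D((display_w - side) / 2.0, (display_h - side) / 2.0)
    return scale, offset
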