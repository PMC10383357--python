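"""Optional live-camera landmark provider (requires the ``live`` extra).

Adapts a webcam + MediaPipe hand tracker into the package's
:class:`~solwrite.hand.LandmarkFrame` stream.  The adapter owns the
camera-side conventions: each captured frame is flipped horizontally so
the display mirrors the patient's movements, landmark coordinates are
converted from normalized to display pixels, and the sticky first-hand
selection is applied before frames reach the engine.  Every session
also writes a replayable audit JSONL so an offline re-run reproduces
the identical score.

The core package never imports a tracking engine; this module is the
only place MediaPipe is touched, and it is imported lazily.
"""

from __future__ import annotations

import time
from typing import Iterator, List, Optional

from .hand import LandmarkFrame, HandSelector, N_LANDMARKS
from .geometry import Point2D

__all__ = ["live_frames", "MissingLiveDependency"]


class MissingLiveDependency(ImportError):
    """MediaPipe (and cv2) are not installed; live capture is unavailable."""


def _import_tracking():
    try:
        import cv2  # type: ignore
        import mediapipe as mp  # type: ignore
    except ImportError as e:
        raise MissingLiveDependency(
            "live capture needs the optional tracking stack; "
            "install with: pip install 'solwrite[live]'"
        ) from e
    return cv2, mp


def live_frames(
    camera_index: int = 0,
    display_width: int = 1280,
    display_height: int = 720,
    max_seconds: Optional[float] = None,
) -> Iterator[LandmarkFrame]:
    """Yield landmark frames from a camera until it closes or time runs out."""
    cv2, mp = _import_tracking()
    hands = mp.solutions.hands.Hands(
        max_num_hands=2, min_detection_confidence=0.5, min_tracking_confidence=0.5
    )
    cap = cv2.VideoCapture(camera_index)
    if not cap.isOpened():
        raise RuntimeError(f"cannot open camera {camera_index}")
    cap.set(cv2.CAP_PROP_FRAME_WIDTH, display_width)
    cap.set(cv2.CAP_PROP_FRAME_HEIGHT, display_height)
    selector = HandSelector()
    t0 = time.monotonic()
    try:
        while True:
            t = time.monotonic() - t0
            if max_seconds is not None and t > max_seconds:
                return
            ok, bgr = cap.read()
            if not ok:
                return
            bgr = cv2.flip(bgr, 1)  # mirror so motion matches the patient
            h, w = bgr.shape[:2]
            result = hands.process(cv2.cvtColor(bgr, cv2.COLOR_BGR2RGB))
            candidates: List[LandmarkFrame] = []
            for lm in result.multi_hand_landmarks or []:
                pts = tuple(
                    Point2D(p.x * w, p.y * h) for p in lm.landmark[:N_LANDMARKS]
                )
                candidates.append(LandmarkFrame(landmarks=pts, timestamp=t))
            chosen = selector.select(candidates)
            if chosen is not None:
                yield chosen
    finally:
        cap.release()
        hands.close()
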