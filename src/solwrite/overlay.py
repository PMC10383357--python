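"""Audit-image rendering.

Color code: green segments for the shape's path, a red dot at the start
point, a blue dot at the end point, and pink for the patient's drawn
trace.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image, ImageDraw

from .detection import Shape, ShapeImage

__all__ = ["render_overlay", "render_trace_overlay"]

GREEN = (0, 200, 0)
RED = (220, 0, 0)
BLUE = (0, 80, 220)
PINK = (255, 105, 180)


def render_overlay(
    shape: Shape,
    background: Optional[ShapeImage] = None,
    size: Tuple[int, int] = (512, 512),
    dot_radius: float = 8.0,
) -> Image.Image:
    """Draw the detected shape: green segments, red start, blue end."""
    if background is not None:
        im = Image.fromarray(background.pixels).convert("RGB")
    else:
        im = Image.new("RGB", size, (255, 255, 255))
    d = ImageDraw.Draw(im)
    for s in shape.segments:
        d.line([(s.p0.x, s.p0.y), (s.p1.x, s.p1.y)], fill=GREEN, width=3)
    for p, color in ((shape.end, BLUE), (shape.start, RED)):
        d.ellipse(
            [p.x - dot_radius, p.y - dot_radius, p.x + dot_radius, p.y + dot_radius],
            fill=color,
        )
    return im


def render_trace_overlay(
    shape: Shape,
    trace_points: Sequence[Tuple[float, float]],
    background: Optional[ShapeImage] = None,
    size: Tuple[int, int] = (512, 512),
) -> Image.Image:
    """Shape overlay plus the drawn path in pink."""
    im = render_overlay(shape, background=background, size=size)
    d = ImageDraw.Draw(im)
    if len(trace_points) >= 2:
        d.line([(x, y) for x, y in trace_points], fill=PINK, width=3)
    elif trace_points:
        x, y = trace_points[0]
        d.ellipse([x - 2, y - 2, x + 2, y + 2], fill=PINK)
    return im
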