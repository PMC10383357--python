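"""Detect a tracing shape from a rendered black-and-white glyph.

Renders the built-in letter-M fixture (four straight strokes), runs the
full detection pipeline (Canny edges -> probabilistic Hough -> duplicate
merge -> topology -> start/end), and prints what was recovered.  The
printed segment count should equal the number of strokes the glyph was
drawn with; the perimeter is the total path length a patient must trace.
"""

from solwrite.detection import build_shape, detect_edges, extract_raw_segments, preprocess_image
from solwrite.fixtures import builtin_stroke_spec, render_shape_image
from solwrite.overlay import render_overlay

spec = builtin_stroke_spec("M")
img, truth = render_shape_image(spec)

raw = extract_raw_segments(detect_edges(preprocess_image(img)), rng_seed=0)
shape = build_shape(img, rng_seed=0, name="M")

print(f"raw Hough segments:    {len(raw)} (over-detection is expected)")
print(f"after duplicate merge: {len(shape.segments)} segments, topology {shape.topology}")
print(f"perimeter: {shape.perimeter:.1f} px (analytic truth {truth.perimeter:.1f} px)")
print(f"start (red dot):  ({shape.start.x:.0f}, {shape.start.y:.0f})  <- bottom-left foot")
print(f"end   (blue dot): ({shape.end.x:.0f}, {shape.end.y:.0f})  <- bottom-right foot")

render_overlay(shape, background=img).save("m_overlay.png")
print("wrote m_overlay.png (green path, red start, blue end)")
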