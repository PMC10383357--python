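"""Shape detection: black-and-white image -> interactive tracing target.

Pipeline: preprocess (512x512 binarization) -> Canny edges -> probabilistic
Hough line segments -> duplicate merging -> topology classification ->
start/end assignment.  The result is a :class:`Shape`: an ordered list of
merged segments with an open/closed topology, a start point, an end point
and a perimeter length, ready for collision checking by the trace engine.

Input constraints: the image must be black strokes on a white background,
contain straight lines only, and is resampled to 512x512 before detection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from PIL import Image
from skimage.feature import canny
from skimage.transform import probabilistic_hough_line

from .geometry import Point2D, Segment, angle_difference

__all__ = [
    "WORKING_SIZE",
    "DetectionParams",
    "ShapeImage",
    "Shape",
    "ShapeValidationError",
    "DetectionError",
    "load_image",
    "preprocess_image",
    "detect_edges",
    "extract_raw_segments",
    "merge_duplicate_segments",
    "classify_topology",
    "assign_endpoints",
    "order_path",
    "build_shape",
]

WORKING_SIZE = 512  # final working resolution, pixels per side


class ShapeValidationError(ValueError):
    """Input image violates the black-and-white straight-line constraints."""


class DetectionError(RuntimeError):
    """A detection stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the detection pipeline.

    Canny hysteresis thresholds are on the 0-255 gradient scale; the
    defaults (50, 150) with a 3-tap Sobel derivative suit near-binary
    glyphs.  Hough and merge tolerances default to values suitable for
    3-5 px strokes on a 512x512 canvas.
    """

    canny_low: float = 50.0
    canny_high: float = 150.0
    canny_sigma: float = 1.0  # Gaussian presmoothing, ~3x3 Sobel support
    hough_threshold: int = 30  # accumulator votes
    hough_min_length: int = 30  # px
    hough_max_gap: int = 10  # px
    hough_angle_step_deg: float = 1.0
    merge_midpoint_tol: float = 15.0  # D_tol, px
    merge_angle_tol_deg: float = 5.0  # A_tol
    junction_tol: float = 12.0  # J_tol, px: endpoint snap distance
    max_midgray_fraction: float = 0.05


@dataclass(frozen=True)
class ShapeImage:
    """A grayscale raster holding the shape to be traced."""

    pixels: np.ndarray  # 2-D uint8, 0=black stroke, 255=white background

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class Shape:
    """A detected tracing target.

    ``segments`` are ordered along the trace path from ``start`` to
    ``end``.  For a closed shape the path is a cycle and start == end.
    ``perimeter`` is the sum of segment lengths in pixels.
    """

    segments: Tuple[Segment, ...]
    topology: str  # "open" | "closed"
    start: Point2D
    end: Point2D
    perimeter: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.topology not in ("open", "closed"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.perimeter <= 0:
            raise ValueError("perimeter must be positive")

    def to_dict(self) -> Dict:
        return {
            "name": self.name,
            "topology": self.topology,
            "segments": [
                [[s.p0.x, s.p0.y], [s.p1.x, s.p1.y]] for s in self.segments
            ],
            "start": [self.start.x, self.start.y],
            "end": [self.end.x, self.end.y],
            "perimeter": self.perimeter,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "Shape":
        segs = tuple(
            Segment(Point2D(*p0), Point2D(*p1)) for p0, p1 in d["segments"]
        )
        return cls(
            segments=segs,
            topology=d["topology"],
            start=Point2D(*d["start"]),
            end=Point2D(*d["end"]),
            perimeter=float(d["perimeter"]),
            name=d.get("name", ""),
        )

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path) -> "Shape":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def scaled(self, scale: float, offset: Point2D) -> "Shape":
        """Uniformly scale and translate the shape into display coordinates."""

        def tp(p: Point2D) -> Point2D:
            return Point2D(p.x * scale + offset.x, p.y * scale + offset.y)

        return Shape(
            segments=tuple(Segment(tp(s.p0), tp(s.p1)) for s in self.segments),
            topology=self.topology,
            start=tp(self.start),
            end=tp(self.end),
            perimeter=self.perimeter * scale,
            name=self.name,
        )


# ---------------------------------------------------------------------------
# pipeline stages


def load_image(path) -> ShapeImage:
    """Read a PNG/BMP/JPEG file into a grayscale ShapeImage."""
    try:
        with Image.open(path) as im:
            return ShapeImage(np.asarray(im.convert("L"), dtype=np.uint8))
    except FileNotFoundError:
        raise
    except OSError as e:  # undecodable file
        raise OSError(f"cannot read image {path}: {e}") from e


def preprocess_image(
    raw: ShapeImage, params: DetectionParams = DetectionParams()
) -> ShapeImage:
    """Resample to 512x512 and binarize; reject non-compliant input.

    Inputs with more than ``max_midgray_fraction`` mid-gray pixels (gray
    gradients, photographs) are rejected: the test requires a black-on-
    white line drawing.  An image with no black content is also rejected.
    """
    px = raw.pixels
    if px.ndim != 2:
        raise ShapeValidationError("image must be single-channel grayscale")
    midgray = np.mean((px > 40) & (px < 215))
    if midgray > params.max_midgray_fraction:
        raise ShapeValidationError(
            "image must be in black and white: "
            f"{midgray:.0%} of pixels are mid-gray (limit "
            f"{params.max_midgray_fraction:.0%})"
        )
    if px.shape != (WORKING_SIZE, WORKING_SIZE):
        im = Image.fromarray(px).resize(
            (WORKING_SIZE, WORKING_SIZE), Image.Resampling.LANCZOS
        )
        px = np.asarray(im, dtype=np.uint8)
    # Otsu threshold on the resampled image
    from skimage.filters import threshold_otsu

    if px.min() == px.max():
        if px.min() > 127:
            raise ShapeValidationError("no shape content: image is blank")
        raise ShapeValidationError("no shape content: image is uniformly dark")
    t = threshold_otsu(px)
    binary = np.where(px > t, 255, 0).astype(np.uint8)
    if not (binary == 0).any():
        raise ShapeValidationError("no shape content: no black stroke pixels")
    return ShapeImage(binary)


def detect_edges(
    img: ShapeImage, params: DetectionParams = DetectionParams()
) -> np.ndarray:
    """Canny edge map of the preprocessed image.

    Hysteresis thresholds are given on the 0-255 gradient scale and
    rescaled to the [0, 1] float image convention internally.
    """
    return canny(
        img.pixels.astype(float) / 255.0,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low / 255.0,
        high_threshold=params.canny_high / 255.0,
    )


def extract_raw_segments(
    edges: np.ndarray,
    rng_seed: int = 0,
    params: DetectionParams = DetectionParams(),
) -> List[Segment]:
    """Probabilistic Hough transform: edge map -> candidate line segments.

    Over-detection is expected (several near-duplicate candidates per
    true stroke); duplicates are resolved by
    :func:`merge_duplicate_segments`.  The sampling order of the
    probabilistic transform is fixed by ``rng_seed`` so the output is
    reproducible.
    """
    if not edges.any():
        raise DetectionError("hough", "no straight lines detected: empty edge map")
    step = math.radians(params.hough_angle_step_deg)
    theta = np.arange(-math.pi / 2.0, math.pi / 2.0, step)
    lines = probabilistic_hough_line(
        edges,
        threshold=params.hough_threshold,
        line_length=params.hough_min_length,
        line_gap=params.hough_max_gap,
        theta=theta,
        rng=np.random.default_rng(rng_seed),
    )
    if not lines:
        raise DetectionError("hough", "no straight lines detected")
    segs = [
        Segment(Point2D(float(x0), float(y0)), Point2D(float(x1), float(y1)))
        for (x0, y0), (x1, y1) in lines
    ]
    # deterministic order regardless of Hough internals
    segs.sort(key=lambda s: (s.midpoint.y, s.midpoint.x, s.p0.x, s.p0.y))
    return segs


def _merge_group(group: Sequence[Segment]) -> Segment:
    """Fuse near-duplicate segments into one spanning their union extent.

    All endpoints are projected onto the group's mean carrier line
    (anchored at the mean midpoint, oriented at the circular-mean angle);
    the extreme projections become the merged endpoints.
    """
    mx = sum(s.midpoint.x for s in group) / len(group)
    my = sum(s.midpoint.y for s in group) / len(group)
    # circular mean of orientation-free angles (double-angle trick),
    # weighted by length so long segments dominate
    c = sum(math.cos(2 * s.angle) * s.length for s in group)
    sn = sum(math.sin(2 * s.angle) * s.length for s in group)
    ang = math.atan2(sn, c) / 2.0 % math.pi
    ux, uy = math.cos(ang), math.sin(ang)
    ts = []
    for s in group:
        for p in (s.p0, s.p1):
            ts.append((p.x - mx) * ux + (p.y - my) * uy)
    t0, t1 = min(ts), max(ts)
    p0 = Point2D(mx + t0 * ux, my + t0 * uy)
    p1 = Point2D(mx + t1 * ux, my + t1 * uy)
    if t1 > t0:
        return Segment(p0, p1)
    return group[0]  # fully coincident degenerate group


def merge_duplicate_segments(
    raw: Sequence[Segment], params: DetectionParams = DetectionParams()
) -> List[Segment]:
    """Collapse duplicate Hough detections of the same stroke.

    Two segments are duplicates when their midpoints are closer than the
    midpoint tolerance AND their orientation-free angles differ by less
    than the angle tolerance.  Duplicate groups are closed transitively,
    then each group is fused by :func:`_merge_group`.  The operation is
    idempotent and never increases the segment count.
    """
    if not raw:
        raise ValueError("merge_duplicate_segments requires segments")
    segs = list(raw)
    a_tol = math.radians(params.merge_angle_tol_deg)

    def duplicates(a: Segment, b: Segment) -> bool:
        if angle_difference(a.angle, b.angle) >= a_tol:
            return False
        if a.midpoint.distance_to(b.midpoint) < params.merge_midpoint_tol:
            return True
        # collinear overlapping pieces of one stroke: midpoints may be far
        # apart, but each lies near the other's carrier extent
        from .geometry import point_segment_distance

        return (
            point_segment_distance(a.midpoint, b) < params.merge_midpoint_tol
            or point_segment_distance(b.midpoint, a) < params.merge_midpoint_tol
        )

    # transitive closure via union-find, then fuse; iterate to fixpoint
    # because fused segments can become duplicates of each other
    while True:
        n = len(segs)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if duplicates(segs[i], segs[j]):
                    parent[find(i)] = find(j)
        groups: Dict[int, List[Segment]] = {}
        for i, s in enumerate(segs):
            groups.setdefault(find(i), []).append(s)
        merged = [_merge_group(g) for g in groups.values()]
        merged.sort(key=lambda s: (s.midpoint.y, s.midpoint.x))
        if len(merged) == len(segs):
            return merged
        segs = merged


def _snap_junctions(
    segments: Sequence[Segment], tol: float
) -> Tuple[List[Segment], List[Point2D], List[List[int]]]:
    """Cluster segment endpoints into shared vertices.

    Endpoints within ``tol`` of each other are replaced by their cluster
    mean.  Returns the snapped segments, the vertex list, and for each
    vertex the indices of incident segments.
    """
    pts: List[Point2D] = []
    for s in segments:
        pts.extend((s.p0, s.p1))
    clusters: List[List[int]] = []
    assignment = [-1] * len(pts)
    for i, p in enumerate(pts):
        for ci, cluster in enumerate(clusters):
            if any(p.distance_to(pts[j]) <= tol for j in cluster):
                cluster.append(i)
                assignment[i] = ci
                break
        else:
            assignment[i] = len(clusters)
            clusters.append([i])
    verts = [
        Point2D(
            sum(pts[j].x for j in c) / len(c), sum(pts[j].y for j in c) / len(c)
        )
        for c in clusters
    ]
    snapped = []
    incident: List[List[int]] = [[] for _ in verts]
    for si, s in enumerate(segments):
        a, b = assignment[2 * si], assignment[2 * si + 1]
        snapped.append(Segment(verts[a], verts[b]))
        incident[a].append(si)
        if b != a:
            incident[b].append(si)
    return snapped, verts, incident


def classify_topology(
    segments: Sequence[Segment], params: DetectionParams = DetectionParams()
) -> str:
    """Classify the merged segments as an open path or a closed loop.

    Closed: every junction vertex joins exactly two segment endpoints and
    the segments form a single cycle (e.g. a triangle or rectangle).
    Open: exactly two vertices have a single incident segment (the free
    ends of the trace, e.g. the letter M).  Anything disconnected or
    branching is rejected: the test needs one traceable path.
    """
    snapped, verts, incident = _snap_junctions(segments, params.junction_tol)
    if not _single_component(snapped, incident):
        raise DetectionError("topology", "shape is not a single connected trace")
    degrees = [len(i) for i in incident]
    if all(d == 2 for d in degrees):
        return "closed"
    if sorted(degrees).count(1) == 2 and all(d <= 2 for d in degrees):
        return "open"
    if any(d > 2 for d in degrees):
        raise DetectionError("topology", "trace is not a single path: branching junction")
    return "open"


def _single_component(segments: Sequence[Segment], incident: Sequence[Sequence[int]]) -> bool:
    if not segments:
        return False
    seen = {0}
    stack = [0]
    while stack:
        si = stack.pop()
        for vi, inc in enumerate(incident):
            if si in inc:
                for sj in inc:
                    if sj not in seen:
                        seen.add(sj)
                        stack.append(sj)
    return len(seen) == len(segments)


def assign_endpoints(
    segments: Sequence[Segment],
    topology: str,
    params: DetectionParams = DetectionParams(),
) -> Tuple[Point2D, Point2D]:
    """Determine the trace's start and end points.

    Open shapes: among the two free (degree-1) endpoints, the start is
    the bottom-leftmost (max y, ties to min x) and the end the remaining
    one.  Closed shapes: the start is the bottom-leftmost junction
    vertex, and the end coincides with it (the trace is a loop).
    """
    snapped, verts, incident = _snap_junctions(segments, params.junction_tol)
    if topology == "closed":
        start = max(verts, key=lambda p: (p.y, -p.x))
        return start, start
    free = [v for v, inc in zip(verts, incident) if len(inc) == 1]
    if len(free) != 2:
        raise DetectionError(
            "endpoints", f"trace is not a single path: {len(free)} free endpoints"
        )
    start = max(free, key=lambda p: (p.y, -p.x))
    end = free[0] if free[1] is start else free[1]
    return start, end


def order_path(
    segments: Sequence[Segment],
    topology: str,
    start: Point2D,
    params: DetectionParams = DetectionParams(),
) -> List[Segment]:
    """Order segments along the trace path from the start point.

    Each returned segment is directed along the walk.  For a closed
    shape the walk direction is chosen so the second vertex has the
    smaller x, which makes the ordering deterministic.
    """
    snapped, verts, incident = _snap_junctions(segments, params.junction_tol)
    vstart = min(range(len(verts)), key=lambda i: verts[i].distance_to(start))
    path: List[Segment] = []
    used = set()
    cur = vstart

    def other_vertex(si: int, vi: int) -> int:
        s = snapped[si]
        a = min(range(len(verts)), key=lambda i: verts[i].distance_to(s.p0))
        b = min(range(len(verts)), key=lambda i: verts[i].distance_to(s.p1))
        return b if a == vi else a

    if topology == "closed":
        # choose the incident segment whose far vertex has smaller x
        first = min(
            incident[vstart], key=lambda si: verts[other_vertex(si, vstart)].x
        )
        nxt_candidates = [first]
    else:
        nxt_candidates = list(incident[cur])
    while True:
        options = [si for si in nxt_candidates if si not in used]
        if not options:
            break
        si = options[0]
        used.add(si)
        nv = other_vertex(si, cur)
        path.append(Segment(verts[cur], verts[nv]))
        cur = nv
        nxt_candidates = list(incident[cur])
    if len(path) != len(segments):
        raise DetectionError("ordering", "could not walk all segments in one path")
    return path


def build_shape(
    raw: ShapeImage,
    rng_seed: int = 0,
    params: DetectionParams = DetectionParams(),
    name: str = "",
) -> Shape:
    """Full detection pipeline: raw image -> traced Shape.

    Stage errors propagate with the failing stage's name attached.
    """
    img = preprocess_image(raw, params)
    edges = detect_edges(img, params)
    raw_segs = extract_raw_segments(edges, rng_seed, params)
    merged = merge_duplicate_segments(raw_segs, params)
    topology = classify_topology(merged, params)
    start, end = assign_endpoints(merged, topology, params)
    ordered = order_path(merged, topology, start, params)
    perimeter = sum(s.length for s in ordered)
    return Shape(
        segments=tuple(ordered),
        topology=topology,
        start=start,
        end=end,
        perimeter=perimeter,
        name=name,
    )
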