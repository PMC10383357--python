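# Methods

This note documents the models, parameter choices and numerical
conventions behind `solwrite`, and what its synthetic testbed does and
does not establish about real camera data.

## Coordinate and angle conventions

All coordinates are image-style pixels: origin top-left, y increasing
downward, so "bottom" means larger y throughout (the start of an open
shape is its bottom-*left* free end, i.e. maximal y, ties broken toward
minimal x).  Line orientation is represented as an angle in [0, π)
rather than a slope: vertical strokes then need no special casing, a
segment and its reverse have the same orientation, and "slope
difference" tests become circular angle distances min(Δ, π−Δ).

The signed deviation of a drawing point from a segment uses the
carrier line (the infinite line through the endpoints), positive on the
left of the p0→p1 walk direction.  The sign convention is arbitrary;
only relative consistency matters, since the statistic of interest is a
mean.  Collision *legality*, by contrast, uses the clamped segment
distance, so overshooting past a free endpoint by more than the radius
is out of bounds even though the carrier-line distance may be small.

## Shape detection

Pipeline: binarize → Canny → probabilistic Hough → duplicate merge →
junction snap → topology → endpoints → path ordering.

- **Binarization.** Inputs are resampled to the 512×512 working
  resolution and thresholded with Otsu.  Inputs whose mid-gray pixel
  fraction exceeds 5% before thresholding (photographs, gradients) are
  rejected: the test is defined on black-on-white line drawings.
- **Canny.** Hysteresis thresholds 50/150 expressed on the 0–255
  gradient scale (converted internally to scikit-image's [0, 1] float
  convention), Gaussian σ = 1 — a 3-tap-Sobel-scale derivative suited
  to near-binary glyphs.
- **Hough.** Probabilistic transform, 1° angular resolution,
  accumulator threshold 30 votes, minimum segment length 30 px, maximum
  gap 10 px.  These are standard starting values for 3–5 px strokes on
  a 512×512 canvas and are exposed in `DetectionParams`.  The
  transform's random sampling is driven by an explicit seed (default 0),
  so a fixed image and seed give a bit-identical shape.  The raw
  segment count is parameter-dependent and only bounded below by the
  true stroke count; the post-merge count is the meaningful output.
- **Duplicate merge.** Two segments are duplicates when their midpoints
  lie within D_tol = 15 px *and* their orientations differ by less than
  A_tol = 5°; collinear fragments of one long stroke are also captured
  by testing each midpoint against the other segment's extent.
  Duplicate groups are closed transitively (union-find) and each group
  is fused by projecting all endpoints onto the group's length-weighted
  mean carrier line and keeping the extreme projections — this
  preserves the union extent of the stroke.  The pass iterates to a
  fixpoint, so the operation is idempotent and never increases the
  count.
- **Topology.** Endpoints within J_tol = 12 px snap into shared
  vertices (replaced by the cluster mean).  A single cycle with all
  vertex degrees 2 is *closed*; exactly two degree-1 vertices is
  *open*; disconnected or branching inputs are rejected — the test
  needs one traceable path.
- **Endpoints and ordering.** Open: start = bottom-leftmost free
  endpoint, end = the other free endpoint.  Closed: start = end =
  bottom-leftmost vertex, walk direction chosen so the second vertex
  has the smaller x (deterministic tie-break).

## Hand model and session engine

Frames carry 21 landmarks in the MediaPipe numbering; only 4 (thumb
tip), 8 (index tip) and 12 (middle tip) drive the engine.  The landmark
*source* is a provider interface — JSONL replay, the simulator, or the
optional live adapter — so the core never imports a tracking engine,
and detector-side concerns (smoothing, mirroring the camera image,
normalized-to-pixel conversion) live in the adapter.

- **Pinch threshold** τ = 60 px default, strict inequality on both the
  thumb–index and thumb–middle distances.  The value is a calibration
  for a hand ~50 cm from a 1280×720 camera and is configurable; no
  published value exists, and pinch monotonicity in τ is what the tests
  pin down.
- **Drawing radius** r ∈ [20, 40] px, enforced at configuration and at
  the drawing point.  20 px is the strictest clinically used setting;
  widening the disc is the built-in difficulty adjustment.
- **Arming.**  IDLE → TRACING when a pinched frame puts the index tip
  within the end-vicinity distance of the start dot.  End vicinity
  defaults to the drawing radius (the on-screen dot size is not
  standardized; the radius is the natural proxy).
- **Per-frame order** while TRACING: timeout (> 60 s) → hand loss
  (inter-frame gap > 0.25 s) → grip check → legality.  The 0.25 s gap
  tolerance forgives isolated dropped detections at 60 fps without
  letting the hand wander unobserved.
- **Drawn length** accumulates the distance between successive
  *projections* of the drawing point onto the matched segment, not raw
  fingertip path length: perpendicular jitter then contributes nothing
  to progress (it would otherwise inflate "distance drawn"), and the
  per-frame advance is capped at 3r so a teleporting outlier frame
  cannot claim a stretch of the shape.  A consequence used by the
  tests: under the simulator's perpendicular-only noise, drawn length
  tracks true arc length exactly.
- **Completion** requires drawn length ≥ 0.9 × perimeter ("closely
  matches"; the fraction is configurable) *and* the index tip within
  the end vicinity.  For closed shapes end = start; the length
  condition is what prevents instant completion at the shared dot.
- **Timeout semantics.**  At 60 s the session ends with outcome
  *partial* rather than failed.  The scoring table awards 1 point for a
  partial performance within 60 s, which requires partial sessions to
  survive the time limit; treating timeout as failure would make that
  row unreachable.
- Deviations are logged against the nearest segment only, including at
  corners where two segments are nearly equidistant; see Limitations.

## Scoring and spasticity

Score bands for completed traces are the half-open intervals [0, 20) →
4, [20, 40) → 3, [40, 60] → 2 ("within 40 s but not less than 20 s"
read as 20 ≤ t < 40, and "within 20 s" as t < 20); partial traces score
1 only when strictly more than 1/3 of the perimeter was covered
("beyond 1/3"); every failure scores 0.  The 2-vs-3 distinction uses
time only; qualitative "difficulty" judgments of the paper-and-pen
original are not modeled.  A grid scan in the tests confirms the
partition has exactly the boundaries {20 s, 40 s} and {1/3}.

Spasticity is defined on the *signed* per-frame deviations.  Because a
symmetric tremor cancels in the signed mean, both statistics are
reported: the signed mean captures systematic drift to one side of the
line, the mean absolute deviation is the headline tremor magnitude.
For zero-mean Gaussian tremor of standard deviation σ the mean absolute
deviation estimates the folded-normal mean σ√(2/π) — the closed form
the synthetic acceptance surface is built on.

Results are appended to a UTF-8, RFC-4180 CSV, one row per session,
header written once.

## Synthetic testbed

The renderer rasterizes known stroke lists (letter M with four strokes,
a rectangle, the Greek capital Π with three, a triangle) at 4 px width
and returns the analytic ground-truth shape, so detection can be judged
against exact geometry (topology, count, perimeter within 2%, 3 px
Hausdorff per segment).

The simulator moves the index fingertip along the analytic path at
constant speed, 60 fps, with *perpendicular-only* Gaussian noise —
chosen so tremor has a closed-form expectation and does not change
trace speed.  The remaining 18 landmarks ride on a rigid, anatomically
plausible right-hand template; only the three pinch landmarks matter.
Scripted events inject the three failure modes: `release_pinch` (thumb
and middle fingertips displaced 200 px), `jump_off_shape` (index tip
displaced 200 px perpendicular for one frame, toward whichever side
lies farther from the whole shape — a purely perpendicular jump can
land on a neighboring stroke of glyphs like M), `drop_hand` (0.5 s of
frames suppressed).

Problem sizes used by the tests and the acceptance script: 512×512
images, sessions of roughly 900–3700 frames (15–61 simulated seconds at
60 fps), tremor sweeps σ = 1–8 px at ≥ 2000 logged frames per level.

What passing does **not** show about real data: the simulator has no
landmark estimation error model (no detector jitter correlated in
time, no occlusion, no depth-dependent scale change), no along-path
speed variation, and the rigid hand template cannot produce
articulation-dependent pinch geometry.  Results on synthetic streams
validate the geometry, the automaton and the statistics — not the
robustness of any particular hand tracker.

## Known limitations

- Straight lines only; curved or multi-component shapes are rejected by
  design.
- Near junctions the deviation is logged against the nearest segment,
  which slightly shrinks the mean absolute deviation when tremor
  straddles a corner: the recovered slope of mean|dev| vs σ runs ~3–6%
  below √(2/π) on the M at σ ≤ 8 px, within the 10% band the tests
  assert.
- The merge tolerances assume strokes at least ~30 px long and corner
  angles above ~5°; glyphs violating that can under- or over-merge.
- Elapsed time is measured from the arming frame to the terminal frame;
  a completed trace therefore registers slightly before the fingertip
  physically touches the end point (the end dot has positive radius).
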