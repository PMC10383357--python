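"""Score a simulated tracing session.

Simulates a patient tracing the letter M in about 15 seconds with a
2 px tremor, replays the landmark stream through the session engine,
and prints the Sollerman sub-test score (0-4) and the spasticity
estimate.  A completion under 20 s earns the maximum score of 4; the
mean absolute deviation is the tremor magnitude in pixels.
"""

from solwrite.engine import SessionConfig, run_session
from solwrite.fixtures import TrajectorySpec, builtin_stroke_spec, ground_truth_shape, simulate_trajectory
from solwrite.scoring import make_report

spec = builtin_stroke_spec("M")
shape = ground_truth_shape(spec)

traj = TrajectorySpec(shape=spec, speed=shape.perimeter / 15.0, tremor_sigma=2.0, seed=42)
frames = simulate_trajectory(traj)
result = run_session(frames, shape, SessionConfig(radius=20.0))
report = make_report(result, shape_name="M", radius=20.0)

print(f"outcome:  {report.outcome.value} in {report.elapsed:.1f} s "
      f"({report.fraction_traced:.0%} of the perimeter traced)")
print(f"score:    {report.score} / 4")
print(f"spasticity: mean |deviation| {report.spasticity_mean_abs:.2f} px, "
      f"signed mean {report.spasticity_mean_signed:+.2f} px")
print("(signed mean near 0 => tremor is symmetric, no systematic drift to one side)")
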