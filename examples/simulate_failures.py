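"""Scripted failure modes and the partial-trace rules.

Every way a session can end without full completion: drawing out of
bounds, losing the tripod pinch, losing the hand, idling after a
partial trace.  Failures always score 0; a partial trace scores 1 only
if more than a third of the shape was covered before the 60 s limit.
"""

from solwrite.engine import SessionConfig, run_session
from solwrite.fixtures import TrajectorySpec, builtin_stroke_spec, ground_truth_shape, half_trace, simulate_trajectory
from solwrite.scoring import assign_score

spec = builtin_stroke_spec("M")
shape = ground_truth_shape(spec)
cfg = SessionConfig(radius=20.0)
speed = shape.perimeter / 30.0  # would finish at 30 s if nothing went wrong

for kind in ("jump_off_shape", "release_pinch", "drop_hand"):
    traj = TrajectorySpec(shape=spec, speed=speed, events=((8.0, kind),))
    res = run_session(simulate_trajectory(traj), shape, cfg)
    print(f"{kind:16s} -> {res.outcome.value:7s} ({res.fail_reason.value}) "
          f"at {res.elapsed:.1f} s, score {assign_score(res)}")

for fraction in (0.30, 0.50):
    traj = TrajectorySpec(shape=spec, speed=speed)
    res = run_session(half_trace(traj, fraction), shape, cfg)
    print(f"partial {fraction:.0%}      -> {res.outcome.value:7s} "
          f"(traced {res.fraction_traced:.0%}), score {assign_score(res)}")
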