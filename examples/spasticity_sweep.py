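"""Recover injected tremor from the deviation log.

Simulates slow traces of the M with perpendicular Gaussian tremor of
known sigma and compares the session's mean absolute deviation with the
folded-normal expectation sigma*sqrt(2/pi).  Agreement shows the
spasticity estimate tracks true tremor magnitude linearly.
"""

import math

from solwrite.engine import SessionConfig, run_session
from solwrite.fixtures import TrajectorySpec, builtin_stroke_spec, ground_truth_shape, simulate_trajectory
from solwrite.scoring import compute_spasticity

spec = builtin_stroke_spec("M")
shape = ground_truth_shape(spec)
cfg = SessionConfig(radius=40.0)  # widest tolerance so tremor never fails the trace
speed = shape.perimeter / 35.0    # ~2100 frames at 60 fps

print("sigma  frames  mean|dev|  sigma*sqrt(2/pi)")
for sigma in (1, 2, 4, 8):
    traj = TrajectorySpec(shape=spec, speed=speed, tremor_sigma=float(sigma), seed=7)
    res = run_session(simulate_trajectory(traj), shape, cfg)
    _, mean_abs = compute_spasticity(res.deviations)
    print(f"{sigma:5d}  {len(res.deviations):6d}  {mean_abs:9.3f}  {sigma * math.sqrt(2 / math.pi):9.3f}")
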