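"""Session state machine: arming, legality, failure, timeout, completion."""

import math
from dataclasses import replace

import pytest

from solwrite import fixtures
from solwrite.engine import (
    FailReason,
    Outcome,
    Phase,
    SessionConfig,
    SessionState,
    StreamError,
    completion_check,
    compute_shape_transform,
    finalize,
    fraction_traced,
    run_session,
    step,
    try_arm,
)
from solwrite.geometry import Point2D
from tests.test_hand import make_frame
from solwrite.hand import INDEX_TIP, MIDDLE_TIP, THUMB_TIP


@pytest.fixture
def cfg():
    return SessionConfig(radius=20.0, pinch_threshold=60.0)


def pinched_at(x, y, t=0.0):
    """A pinched tripod frame with the index fingertip at (x, y)."""
    return make_frame(
        t, {INDEX_TIP: (x, y), THUMB_TIP: (x - 10, y + 18), MIDDLE_TIP: (x + 12, y + 14)},
    )


def open_at(x, y, t=0.0):
    return make_frame(
        t, {INDEX_TIP: (x, y), THUMB_TIP: (x + 300, y), MIDDLE_TIP: (x + 300, y)}
    )


class TestArming:
    def test_pinched_on_start_dot_arms(self, m_truth, cfg):
        s0 = SessionState()
        f = pinched_at(m_truth.start.x, m_truth.start.y)
        s1 = try_arm(s0, f, cfg, m_truth)
        assert s1.phase is Phase.TRACING
        assert s1.start_time == f.timestamp

    def test_pinched_far_from_start_stays_idle(self, m_truth, cfg):
        s1 = try_arm(
            SessionState(),
            pinched_at(m_truth.start.x + 100, m_truth.start.y),
            cfg,
            m_truth,
        )
        assert s1.phase is Phase.IDLE

    def test_unpinched_on_start_dot_stays_idle(self, m_truth, cfg):
        s1 = try_arm(
            SessionState(), open_at(m_truth.start.x, m_truth.start.y), cfg, m_truth
        )
        assert s1.phase is Phase.IDLE


class TestStep:
    def arm(self, m_truth, cfg):
        return try_arm(
            SessionState(),
            pinched_at(m_truth.start.x, m_truth.start.y, 0.0),
            cfg,
            m_truth,
        )

    def test_off_shape_draw_point_fails_out_of_bounds(self, m_truth, cfg):
        s = self.arm(m_truth, cfg)
        s = step(s, pinched_at(m_truth.start.x + 50, m_truth.start.y + 50, 0.02), cfg, m_truth)
        assert s.phase is Phase.FAILED
        assert s.fail_reason is FailReason.OUT_OF_BOUNDS

    def test_released_pinch_fails_grip_lost(self, m_truth, cfg):
        s = self.arm(m_truth, cfg)
        s = step(s, open_at(m_truth.start.x, m_truth.start.y, 0.02), cfg, m_truth)
        assert s.phase is Phase.FAILED
        assert s.fail_reason is FailReason.GRIP_LOST

    def test_long_frame_gap_fails_hand_lost(self, m_truth, cfg):
        s = self.arm(m_truth, cfg)
        s = step(s, pinched_at(m_truth.start.x, m_truth.start.y, 0.6), cfg, m_truth)
        assert s.phase is Phase.FAILED
        assert s.fail_reason is FailReason.HAND_LOST

    def test_short_frame_gap_tolerated(self, m_truth, cfg):
        s = self.arm(m_truth, cfg)
        s = step(s, pinched_at(m_truth.start.x, m_truth.start.y - 2, 0.2), cfg, m_truth)
        assert s.phase is Phase.TRACING

    def test_past_time_limit_times_out(self, m_truth, cfg):
        s = self.arm(m_truth, cfg)
        s = step(s, pinched_at(m_truth.start.x, m_truth.start.y, 0.1), cfg, m_truth)
        s = replace(s, last_time=60.3)
        s = step(s, pinched_at(m_truth.start.x, m_truth.start.y, 60.5), cfg, m_truth)
        assert s.phase is Phase.TIMED_OUT

    def test_non_monotone_timestamp_rejected(self, m_truth, cfg):
        s = self.arm(m_truth, cfg)
        s = step(s, pinched_at(m_truth.start.x, m_truth.start.y - 1, 0.1), cfg, m_truth)
        with pytest.raises(StreamError, match="non-monotone"):
            step(s, pinched_at(m_truth.start.x, m_truth.start.y, 0.05), cfg, m_truth)

    def test_legal_frames_log_deviations(self, m_truth, cfg):
        s = self.arm(m_truth, cfg)
        for i in range(1, 6):
            s = step(
                s,
                pinched_at(m_truth.start.x + 3, m_truth.start.y - 5 * i, i * 0.02),
                cfg,
                m_truth,
            )
        assert s.phase is Phase.TRACING
        assert len(s.deviations) == 5
        assert all(abs(d) == pytest.approx(3.0, abs=0.2) for d in s.deviations)


class TestCompletion:
    def test_full_length_at_end_completes(self, m_truth, cfg):
        s = SessionState(
            phase=Phase.TRACING, start_time=0.0, drawn_length=m_truth.perimeter
        )
        f = pinched_at(m_truth.end.x, m_truth.end.y, 10.0)
        assert completion_check(s, f, cfg, m_truth)

    def test_short_trace_at_end_does_not_complete(self, m_truth, cfg):
        s = SessionState(
            phase=Phase.TRACING, start_time=0.0, drawn_length=0.05 * m_truth.perimeter
        )
        f = pinched_at(m_truth.end.x, m_truth.end.y, 10.0)
        assert not completion_check(s, f, cfg, m_truth)

    def test_closed_shape_needs_length_before_completing_at_start(self, cfg):
        """On a loop, standing at the shared start/end dot must not complete."""
        truth = fixtures.ground_truth_shape(fixtures.builtin_stroke_spec("rectangle"))
        assert truth.start == truth.end
        short = SessionState(phase=Phase.TRACING, start_time=0.0, drawn_length=1.0)
        f = pinched_at(truth.start.x, truth.start.y, 1.0)
        assert not completion_check(short, f, cfg, truth)
        full = replace(short, drawn_length=truth.perimeter)
        assert completion_check(full, f, cfg, truth)

    def test_far_from_end_does_not_complete(self, m_truth, cfg):
        s = SessionState(
            phase=Phase.TRACING, start_time=0.0, drawn_length=0.95 * m_truth.perimeter
        )
        f = pinched_at(m_truth.end.x - 200, m_truth.end.y, 10.0)
        assert not completion_check(s, f, cfg, m_truth)


class TestFinalize:
    def test_terminal_mapping(self, m_truth):
        base = SessionState(start_time=0.0, last_time=15.0, drawn_length=m_truth.perimeter)
        done = finalize(replace(base, phase=Phase.COMPLETED), m_truth)
        assert (done.outcome, done.elapsed, done.fraction_traced) == (
            Outcome.COMPLETED,
            15.0,
            1.0,
        )
        to = finalize(
            replace(base, phase=Phase.TIMED_OUT, last_time=60.4,
                    drawn_length=0.6 * m_truth.perimeter),
            m_truth,
        )
        assert to.outcome is Outcome.PARTIAL
        assert to.elapsed == 60.0
        assert to.fraction_traced == pytest.approx(0.6)
        failed = finalize(
            replace(base, phase=Phase.FAILED, fail_reason=FailReason.OUT_OF_BOUNDS,
                    drawn_length=0.8 * m_truth.perimeter),
            m_truth,
        )
        assert failed.outcome is Outcome.FAILED
        assert failed.fraction_traced == pytest.approx(0.8)

    def test_non_terminal_rejected(self, m_truth):
        with pytest.raises(ValueError, match="terminal"):
            finalize(SessionState(phase=Phase.TRACING), m_truth)

    def test_fraction_capped_at_one(self, m_truth):
        s = SessionState(drawn_length=2 * m_truth.perimeter)
        assert fraction_traced(s, m_truth) == 1.0


class TestRunSession:
    @pytest.mark.parametrize("name", sorted(fixtures.BUILTIN_SHAPES))
    @pytest.mark.parametrize("speed", [50.0, 150.0, 300.0])
    def test_noiseless_trace_completes_on_every_builtin(self, name, speed, cfg):
        spec = fixtures.builtin_stroke_spec(name)
        truth = fixtures.ground_truth_shape(spec)
        if truth.perimeter / speed > 59.0:
            pytest.skip("slower than the time limit for this perimeter")
        traj = fixtures.TrajectorySpec(shape=spec, speed=speed)
        res = run_session(fixtures.simulate_trajectory(traj), truth, cfg)
        assert res.outcome is Outcome.COMPLETED
        assert res.fraction_traced >= cfg.length_match_fraction - 0.05

    def test_drawn_length_close_to_perimeter(self, m_truth, cfg):
        spec = fixtures.builtin_stroke_spec("M")
        traj = fixtures.TrajectorySpec(shape=spec, speed=m_truth.perimeter / 20.0)
        res = run_session(fixtures.simulate_trajectory(traj), m_truth, cfg)
        assert res.outcome is Outcome.COMPLETED
        # completion triggers at >= 90% drawn + end vicinity; noiseless
        # tracing tracks the true arc length within 5%
        assert res.fraction_traced * m_truth.perimeter >= 0.9 * m_truth.perimeter
        assert res.fraction_traced == pytest.approx(1.0, abs=0.05)

    def test_replay_is_deterministic(self, m_truth, cfg):
        spec = fixtures.builtin_stroke_spec("M")
        traj = fixtures.TrajectorySpec(
            shape=spec, speed=60.0, tremor_sigma=3.0, seed=11
        )
        frames = fixtures.simulate_trajectory(traj)
        r1 = run_session(frames, m_truth, cfg)
        r2 = run_session(frames, m_truth, cfg)
        assert r1 == r2

    def test_stream_ending_mid_trace_is_hand_lost(self, m_truth, cfg):
        frames = [pinched_at(m_truth.start.x, m_truth.start.y, i * 0.02) for i in range(5)]
        res = run_session(frames, m_truth, cfg)
        assert res.outcome is Outcome.FAILED
        assert res.fail_reason is FailReason.HAND_LOST

    def test_never_armed_stream_fails_with_nothing_traced(self, m_truth, cfg):
        frames = [open_at(50, 50, i * 0.02) for i in range(5)]
        res = run_session(frames, m_truth, cfg)
        assert res.outcome is Outcome.FAILED
        assert res.fraction_traced == 0.0
        assert res.deviations == ()

    def test_audit_log_one_record_per_frame(self, m_truth, cfg):
        spec = fixtures.builtin_stroke_spec("M")
        traj = fixtures.TrajectorySpec(shape=spec, speed=m_truth.perimeter / 15.0)
        frames = fixtures.simulate_trajectory(traj)
        audit = []
        run_session(frames, m_truth, cfg, audit_log=audit)
        assert 0 < len(audit) <= len(frames)
        assert audit[-1]["phase"] == "COMPLETED"


class TestShapeTransform:
    def test_centered_uniform_scale(self):
        scale, offset = compute_shape_transform(1280, 720)
        assert scale == pytest.approx(0.9 * 720 / 512)
        side = scale * 512
        assert offset.x == pytest.approx((1280 - side) / 2)
        assert offset.y == pytest.approx((720 - side) / 2)

    def test_scaled_shape_preserves_relative_geometry(self, m_truth):
        scale, offset = compute_shape_transform(1280, 720)
        scaled = m_truth.scaled(scale, offset)
        assert scaled.perimeter == pytest.approx(m_truth.perimeter * scale)
        assert scaled.topology == m_truth.topology
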