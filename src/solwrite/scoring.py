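"""Sollerman 0-4 scoring and the hand-spasticity (mean deviation) estimate.

Grading follows the standard sub-test scale: 0 when the task could not
be carried out (out-of-bounds drawing, grip loss, or less than a third
of the shape traced), 1 for a partial trace within the 60 s limit, and
for completed traces the score is set by completion time alone:
4 under 20 s, 3 in [20, 40) s, 2 in [40, 60] s.

Spasticity is the mean of the per-frame signed deviations of the
drawing point from the shape's carrier lines.  Because a symmetric
wobble has a signed mean near zero, both the signed mean (systematic
drift to one side) and the mean of absolute deviations (the headline
tremor magnitude) are reported.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

from .engine import FailReason, Outcome, SessionResult

__all__ = ["ScoreReport", "assign_score", "compute_spasticity", "write_results_csv"]

CSV_FIELDS = [
    "session_id",
    "timestamp",
    "shape_name",
    "score",
    "elapsed_s",
    "fraction_traced",
    "spasticity_mean_abs_px",
    "spasticity_mean_signed_px",
    "outcome",
    "radius_px",
]


@dataclass(frozen=True)
class ScoreReport:
    """A scored session, ready for the results CSV."""

    score: int
    spasticity_mean_abs: Optional[float]
    spasticity_mean_signed: Optional[float]
    elapsed: float
    fraction_traced: float
    outcome: Outcome
    fail_reason: FailReason = FailReason.NONE
    shape_name: str = ""
    radius: float = 20.0
    session_id: str = ""
    timestamp: str = ""


def assign_score(result: SessionResult) -> int:
    """Map a session result to the 0-4 sub-test score.

    failed -> 0; partial with fraction <= 1/3 -> 0, fraction > 1/3 -> 1;
    completed -> 4 under 20 s, 3 in [20, 40) s, 2 in [40, 60] s.
    """
    if result.outcome is Outcome.FAILED:
        return 0
    if result.outcome is Outcome.PARTIAL:
        return 1 if result.fraction_traced > 1.0 / 3.0 else 0
    # completed: score by completion time only
    t = result.elapsed
    if t > 60.0:
        raise RuntimeError(
            f"completed session with elapsed {t} s > 60 s: engine invariant broken"
        )
    if t < 20.0:
        return 4
    if t < 40.0:
        return 3
    return 2


def compute_spasticity(
    deviations: Sequence[float],
) -> Tuple[Optional[float], Optional[float]]:
    """Mean signed and mean absolute deviation of the trace, in pixels.

    Returns ``(mean_signed, mean_abs)``; both are ``None`` (with a
    warning) when no deviations were logged, e.g. a session that never
    armed.
    """
    if len(deviations) == 0:
        warnings.warn("no deviations logged; spasticity undefined", stacklevel=2)
        return None, None
    n = len(deviations)
    return sum(deviations) / n, sum(abs(d) for d in deviations) / n


def make_report(
    result: SessionResult,
    shape_name: str = "",
    radius: float = 20.0,
    session_id: str = "",
    timestamp: str = "",
) -> ScoreReport:
    """Score a session result and bundle it into a ScoreReport."""
    with warnings.catch_warnings():
        if len(result.deviations) == 0:
            warnings.simplefilter("ignore")
        mean_signed, mean_abs = compute_spasticity(result.deviations)
    return ScoreReport(
        score=assign_score(result),
        spasticity_mean_abs=mean_abs,
        spasticity_mean_signed=mean_signed,
        elapsed=result.elapsed,
        fraction_traced=result.fraction_traced,
        outcome=result.outcome,
        fail_reason=result.fail_reason,
        shape_name=shape_name,
        radius=radius,
        session_id=session_id,
        timestamp=timestamp,
    )


def write_results_csv(report: ScoreReport, path) -> None:
    """Append one session row to the results CSV; header written once."""
    path = Path(path)
    new_file = not path.exists() or path.stat().st_size == 0
    with open(path, "a", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
        if new_file:
            w.writeheader()
        w.writerow(
            {
                "session_id": report.session_id,
                "timestamp": report.timestamp,
                "shape_name": report.shape_name,
                "score": report.score,
                "elapsed_s": f"{report.elapsed:.6f}",
                "fraction_traced": f"{report.fraction_traced:.6f}",
                "spasticity_mean_abs_px": ""
                if report.spasticity_mean_abs is None
                else f"{report.spasticity_mean_abs:.6f}",
                "spasticity_mean_signed_px": ""
                if report.spasticity_mean_signed is None
                else f"{report.spasticity_mean_signed:.6f}",
                "outcome": report.outcome.value,
                "radius_px": f"{report.radius:g}",
            }
        )
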