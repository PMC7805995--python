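"""Task performance constraints P(r) for the bundled movements.

The optimization is feasible iff ``P(r) <= 0``.  Pointing uses a Boolean
accuracy-and-hold criterion averaged over repeated stochastic runs (P is 0
or 1); the periodic task uses the survived-duration deficit ``T - t_stop``
under a speed-band and height-floor abort rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .plants import PeriodicAbortMonitor, SimResult

__all__ = [
    "PointingCriterion",
    "PeriodicCriterion",
    "pointing_P",
    "periodic_P",
    "estimate_reference_speed",
]


@dataclass(frozen=True)
class PointingCriterion:
    """End-point accuracy inside a goal circle, with a hold condition.

    Feasible iff the across-run mean end-effector position lies strictly
    inside the circle of ``radius`` around ``(x_goal, y_goal)`` AND the
    magnitude of every across-run mean joint velocity is strictly below
    ``vel_threshold``.
    """

    x_goal: float
    y_goal: float
    radius: float = 0.025          # m
    vel_threshold: float = 0.15    # rad/s
    repeats: int = 5

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not self.vel_threshold > 0:
            raise ValueError("velocity threshold must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def pointing_P(results: Sequence[SimResult], criterion: PointingCriterion) -> float:
    """Two-valued pointing performance: 0 (success) or 1 (failure).

    End positions and end velocities are averaged across the ``repeats``
    runs before testing, so controller stochasticity is judged by its mean
    behavior.  Both inequalities are strict: a mean end point exactly on
    the circle fails.
    """
    if len(results) != criterion.repeats:
        raise ValueError(
            f"expected {criterion.repeats} runs, got {len(results)}")
    if any(not r.completed for r in results):
        return 1.0
    mx = float(np.mean([r.x_end for r in results]))
    my = float(np.mean([r.y_end for r in results]))
    mdq = float(np.mean([r.dq_end for r in results]))
    dist2 = (criterion.x_goal - mx) ** 2 + (criterion.y_goal - my) ** 2
    in_circle = dist2 < criterion.radius ** 2
    holds = abs(mdq) < criterion.vel_threshold
    return 0.0 if (in_circle and holds) else 1.0


@dataclass(frozen=True)
class PeriodicCriterion:
    """Walking-like survival criterion: speed band plus height floor.

    The run aborts as soon as the sliding-window mean forward speed leaves
    the ``band`` fraction around ``ref_speed``, or the height analogue
    drops to ``y_min``; the performance value is the missing duration
    ``T - t_stop`` (0 for a run that survives the whole simulation).
    """

    ref_speed: float               # m/s, from the undiscretized reference
    T: float                       # s, full simulation duration
    band: float = 0.06
    y_min: float = 1.24            # m
    window_s: float = 1.0          # s, speed-averaging window (one cycle)

    def __post_init__(self) -> None:
        if not 0 < self.band < 1:
            raise ValueError("band must be in (0, 1)")
        if not self.T > 0:
            raise ValueError("duration T must be positive")

    def make_monitor(self, eval_start: float, dt: float) -> PeriodicAbortMonitor:
        return PeriodicAbortMonitor(
            ref_speed=self.ref_speed, band=self.band, y_min=self.y_min,
            window_s=self.window_s, eval_start=eval_start, dt=dt)


def periodic_P(result: SimResult, criterion: PeriodicCriterion) -> float:
    """Missing duration ``T - t_stop``; feasible iff the run survived."""
    return float(criterion.T - result.t_stop)


def estimate_reference_speed(
    times: np.ndarray, x: np.ndarray
) -> float:
    """Typical forward speed: least-squares slope of x against t."""
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two samples to estimate a speed")
    return float(np.polyfit(times, x, 1)[0])
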