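"""Sprint mechanical metrics: peak/mean power, total work, power decrease.

Total work per 30 s sprint is the time integral of crank power
(trapezoidal rule over the sampled trace), reported in kJ; mean power is
the time average over the sprint window. Session fatigue is summarised by
the power-decrease percentage,

    100 * sum(mean powers) / (best mean power * n_sprints) - 100,

which is 0 when every sprint matches the best one and negative otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PowerTrace

__all__ = ["SprintPerformance", "sprint_metrics", "summary_metrics", "power_decrease"]


@dataclass
class SprintPerformance:
    """Mechanical summary of one sprint."""

    sprint_index: int
    peak_power: float  # W
    mean_power: float  # W
    total_work: float  # kJ
    condition: str = "NOR"

    def __post_init__(self):
        if self.peak_power < self.mean_power - 1e-9:
            raise ValueError("peak_power must be >= mean_power")
        if self.mean_power < 0:
            raise ValueError("mean_power must be >= 0")


def sprint_metrics(
    power: PowerTrace,
    t_start: float,
    duration: float = 30.0,
    sprint_index: int = 0,
    condition: str = "NOR",
) -> SprintPerformance:
    """Peak/mean power and total work over ``[t_start, t_start + duration]``.

    The window endpoints must both be covered by the trace (the closing
    sample is needed by the trapezoidal integral).
    """
    eps = 0.5 / power.sampling_rate
    t_stop = t_start + duration
    sel = (power.time >= t_start - eps) & (power.time <= t_stop + eps)
    t = power.time[sel]
    p = power.power[sel]
    if t.size < 2 or t[0] > t_start + eps or t[-1] < t_stop - eps:
        raise ValueError(
            f"power trace does not cover the sprint window [{t_start:g}, {t_stop:g}] s"
        )
    span = float(t[-1] - t[0])
    work_j = float(np.trapezoid(p, t))
    return SprintPerformance(
        sprint_index=sprint_index,
        peak_power=float(np.max(p)),
        mean_power=work_j / span,
        total_work=work_j / 1000.0,
        condition=condition,
    )


def summary_metrics(
    mean_power: float,
    duration: float = 30.0,
    peak_power: float | None = None,
    sprint_index: int = 0,
    condition: str = "NOR",
) -> SprintPerformance:
    """Build sprint metrics from a per-sprint summary (no trace).

    Total work is ``mean_power * duration`` (kJ); peak defaults to the mean
    when unreported.
    """
    if mean_power < 0:
        raise ValueError("mean_power must be >= 0")
    return SprintPerformance(
        sprint_index=sprint_index,
        peak_power=mean_power if peak_power is None else peak_power,
        mean_power=mean_power,
        total_work=mean_power * duration / 1000.0,
        condition=condition,
    )


def power_decrease(mean_powers) -> float:
    """Power-decrease percentage across a session's sprints (<= 0)."""
    means = np.asarray(mean_powers, dtype=float)
    if means.size == 0:
        raise ValueError("mean_powers must be non-empty")
    if np.any(means <= 0):
        raise ValueError("all mean powers must be > 0")
    return float(100.0 * means.sum() / (means.max() * means.size) - 100.0)
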