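"""Linear model of sprint-onset muscle deoxygenation.

Over the first 10 samples of each sprint (t = 0..9 s at 1 Hz) the TSI drop
is modelled as a straight line,

    mTSI(t) = a * t + TSI0,

where the slope ``a`` (percent/s) is the deoxygenation rate and the
intercept ``TSI0`` is the pre-sprint saturation. Derived quantities:
``a_adj = a / W`` normalises the rate by the sprint's total mechanical work
W (kJ), and ``delta_tsi`` is the TSI range (max - min) over the whole 30 s
sprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocess import Segment

__all__ = [
    "DeoxyFit",
    "DeoxygenationRateModel",
    "fit_linear_deoxy",
    "adjusted_rate",
    "delta_tsi",
]


@dataclass
class DeoxyFit:
    """Result of the linear deoxygenation fit for one sprint."""

    a: float  # percent / s
    tsi0: float  # percent
    r2: float
    r2_defined: bool
    sprint_index: int = 0
    condition: str = "NOR"
    a_adj: float | None = None  # percent / s / kJ
    delta_tsi: float | None = None  # percent


class DeoxygenationRateModel(BaseEstimator, RegressorMixin):
    """Ordinary least squares line through a TSI onset window.

    Fitted attributes
    -----------------
    slope_ : float
        Deoxygenation rate ``a`` in percent/s (negative during a sprint).
    intercept_ : float
        ``TSI0``, the modelled saturation at sprint onset.
    r2_ : float
        ``1 - SS_res / SS_tot`` between the fitted line and the data;
        ``nan`` when the window is constant (``SS_tot = 0``).
    r2_defined_ : bool
        False only in the constant-window degenerate case.
    """

    def __init__(self, expected_points: int | None = 10):
        self.expected_points = expected_points

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("t and y must have equal lengths")
        if t.size < 2:
            raise ValueError("need at least 2 samples to fit a line")
        if self.expected_points is not None and t.size != self.expected_points:
            raise ValueError(
                f"window has {t.size} samples; expected {self.expected_points} "
                "(pass expected_points=None to override)"
            )
        tbar = t.mean()
        ybar = y.mean()
        sxx = float(np.sum((t - tbar) ** 2))
        sxy = float(np.sum((t - tbar) * (y - ybar)))
        sstot = float(np.sum((y - ybar) ** 2))
        if sstot == 0.0:
            # constant window: slope 0, intercept at the value, R^2 undefined
            self.slope_ = 0.0
            self.intercept_ = ybar
            self.r2_ = float("nan")
            self.r2_defined_ = False
        else:
            self.slope_ = sxy / sxx
            self.intercept_ = ybar - self.slope_ * tbar
            ssres = float(np.sum((y - (self.slope_ * t + self.intercept_)) ** 2))
            self.r2_ = 1.0 - ssres / sstot
            self.r2_defined_ = True
        self.n_samples_ = t.size
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.slope_ * t + self.intercept_


def fit_linear_deoxy(window: Segment, total_work: float | None = None, expected_points: int | None = 10) -> DeoxyFit:
    """Fit the onset line to a ``deoxy_window`` segment.

    ``total_work`` (kJ), when given, populates the work-adjusted rate.
    """
    if window.kind != "deoxy_window":
        raise ValueError(f"expected a deoxy_window segment, got {window.kind!r}")
    model = DeoxygenationRateModel(expected_points=expected_points).fit(window.time, window.tsi)
    fit = DeoxyFit(
        a=model.slope_,
        tsi0=model.intercept_,
        r2=model.r2_,
        r2_defined=model.r2_defined_,
        sprint_index=window.sprint_index,
        condition=window.condition,
    )
    if total_work is not None:
        fit.a_adj = adjusted_rate(model.slope_, total_work)
    return fit


def adjusted_rate(a: float, total_work: float) -> float:
    """Work-normalised deoxygenation rate ``a / W`` (percent/s/kJ)."""
    if total_work <= 0:
        raise ValueError(f"total_work must be > 0 kJ, got {total_work}")
    return a / total_work


def delta_tsi(sprint_segment: Segment) -> float:
    """TSI range (max - min) over a full sprint segment, percent."""
    if len(sprint_segment) == 0:
        raise ValueError("empty sprint segment")
    return float(np.max(sprint_segment.tsi) - np.min(sprint_segment.tsi))
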