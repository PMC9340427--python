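"""Synthetic sprint-interval sessions with known ground-truth kinetics.

No public dataset accompanies the study design this package serves, so the
test bench is a generator that emulates a 5-sprint session (30 s all-out,
240 s passive recovery) for each of four conditions: cuff blood-flow
restriction (BFR), gravity-induced BFR (supine, legs elevated), normobaric
hypoxia (HYP) and normoxia (NOR). Per sprint the noiseless TSI signal is
piecewise:

* a pre-sprint plateau at ``TSI0``;
* an exactly linear decline at rate ``a`` over the first 10 s of the
  sprint (the span the linear model fits);
* a smooth slope-continuous exponential easing from the 10 s point down to
  the sprint floor (= the recovery baseline ``TSIb``) for the rest of the
  30 s effort;
* a delayed mono-exponential recovery with parameters (TSIb, A, TD, tau).

White Gaussian noise (sd ``noise_sd``) and a slow random-walk drift are
added on top. The crank-power trace decays exponentially within each
sprint, scaled to hit the drawn mean power, with a linear sprint-to-sprint
fatigue factor producing a realistic power-decrease percentage.

Per-condition parameter distributions are centred on the group means a
NIRS sprint study of this design reports (baseline saturation ordering
NOR ≈ BFR > HYP > G-BFR; delay longest under BFR; time constant longest
under gravity-induced BFR). All randomness flows from one integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import PowerTrace, TSITrace
from .preprocess import CONDITIONS, SessionProtocol
from .reoxy import a_prime as _a_prime
from .reoxy import mrt as _mrt
from .reoxy import predict_reoxy

__all__ = ["SyntheticSpec", "GroundTruth", "default_spec", "generate_session"]

log = logging.getLogger(__name__)

# (mean, sd) per condition, centred on the reported group statistics
_TSI0 = {"BFR": (80.0, 4.4), "G-BFR": (72.4, 8.6), "HYP": (77.6, 3.7), "NOR": (79.2, 4.5)}
_SLOPE = {"BFR": (-2.6, 1.2), "G-BFR": (-2.5, 1.1), "HYP": (-2.5, 1.1), "NOR": (-2.4, 1.0)}
_AMP = {"BFR": (23.6, 7.1), "G-BFR": (30.2, 5.9), "HYP": (28.6, 10.0), "NOR": (27.1, 8.7)}
_TD = {"BFR": (52.6, 40.2), "G-BFR": (24.2, 12.1), "HYP": (18.5, 15.2), "NOR": (14.7, 14.5)}
_TAU = {"BFR": (50.1, 33.8), "G-BFR": (60.8, 53.4), "HYP": (30.9, 16.8), "NOR": (26.7, 15.8)}
_TSIB = {"BFR": (49.0, 4.0), "G-BFR": (39.0, 4.0), "HYP": (46.0, 4.0), "NOR": (49.0, 4.0)}
_PEAK_W = {"BFR": (766.6, 174.2), "G-BFR": (717.8, 135.0), "HYP": (783.0, 149.6), "NOR": (835.4, 176.0)}
_MEAN_W = {"BFR": (551.9, 107.4), "G-BFR": (533.8, 97.6), "HYP": (557.4, 82.8), "NOR": (593.4, 98.6)}


@dataclass
class SyntheticSpec:
    """Generative parameters of a synthetic session.

    Distribution fields are (mean, sd) pairs sampled per sprint (kinetics)
    or per session (power); ``noise_sd`` is the white-noise sd in %TSI and
    ``drift_sd`` the sd of the random-walk drift accumulated over 100 s.
    """

    condition: str = "NOR"
    tsi0: tuple = (79.2, 4.5)  # percent
    slope: tuple = (-2.4, 1.0)  # percent / s
    tsib: tuple = (49.0, 4.0)  # percent
    amp: tuple = (27.1, 8.7)  # percent
    td: tuple = (14.7, 14.5)  # s
    tau: tuple = (26.7, 15.8)  # s
    peak_power: tuple = (835.4, 176.0)  # W
    mean_power: tuple = (593.4, 98.6)  # W
    power_fatigue: float = 0.065  # fractional drop in power per sprint
    noise_sd: float = 1.0  # percent TSI
    drift_sd: float = 0.5  # percent per 100 s
    n_sprints: int = 5
    sprint_duration: float = 30.0
    recovery_duration: float = 240.0
    lead_in: float = 30.0  # pre-session plateau, s
    linear_span: float = 10.0  # exactly-linear sprint onset, s
    seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        for name in ("tsi0", "tsib", "amp", "td", "tau", "peak_power", "mean_power"):
            _, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} sd must be >= 0")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise_sd and drift_sd must be >= 0")
        if self.n_sprints < 1:
            raise ValueError("n_sprints must be >= 1")


def default_spec(condition: str = "NOR", **overrides) -> SyntheticSpec:
    """Spec with per-condition defaults centred on the reported group means."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    spec = SyntheticSpec(
        condition=condition,
        tsi0=_TSI0[condition],
        slope=_SLOPE[condition],
        tsib=_TSIB[condition],
        amp=_AMP[condition],
        td=_TD[condition],
        tau=_TAU[condition],
        peak_power=_PEAK_W[condition],
        mean_power=_MEAN_W[condition],
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass
class GroundTruth:
    """True per-sprint parameters used by the generator."""

    a: np.ndarray
    tsi0: np.ndarray
    tsib: np.ndarray
    amp_a: np.ndarray
    td: np.ndarray
    tau: np.ndarray
    a_prime: np.ndarray
    mrt: np.ndarray
    peak_power: np.ndarray
    mean_power: np.ndarray
    condition: str = "NOR"
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        n = self.a.size
        return pd.DataFrame(
            {
                "condition": [self.condition] * n,
                "sprint_index": np.arange(1, n + 1),
                "a": self.a,
                "tsi0": self.tsi0,
                "tsib": self.tsib,
                "amp_a": self.amp_a,
                "td": self.td,
                "tau": self.tau,
                "a_prime": self.a_prime,
                "mrt": self.mrt,
                "peak_power": self.peak_power,
                "mean_power": self.mean_power,
            }
        )


def _draw_sprint_params(spec: SyntheticSpec, rng: np.random.Generator, max_redraws: int = 100):
    """Draw one sprint's kinetic parameters, redrawing invalid combinations.

    Validity: the 10 s linear extrapolation must sit above the recovery
    floor (so the sprint easing has a positive time constant), TD/tau must
    be positive and the recovery must stay inside [0, 100] %TSI.
    """
    for attempt in range(max_redraws):
        tsi0 = rng.normal(*spec.tsi0)
        a = rng.normal(*spec.slope)
        tsib = rng.normal(*spec.tsib)
        amp = rng.normal(*spec.amp)
        td = rng.normal(*spec.td)
        tau = rng.normal(*spec.tau)
        v10 = tsi0 + spec.linear_span * a
        ok = (
            a < -0.2
            and 40.0 < tsi0 < 98.0
            and 10.0 < tsib < v10 - 2.0
            and 5.0 < amp
            and tsib + amp < 100.0
            and 2.0 <= td < 0.35 * spec.recovery_duration
            and 8.0 <= tau <= 150.0
        )
        if ok:
            if attempt:
                log.debug("parameter draw accepted after %d redraws", attempt)
            return tsi0, a, tsib, amp, td, tau
    # cap reached: clamp a fresh draw into the feasible box
    log.warning("parameter redraw cap reached; clamping draw into feasible ranges")
    tsi0 = float(np.clip(rng.normal(*spec.tsi0), 45.0, 95.0))
    a = float(np.clip(rng.normal(*spec.slope), -5.0, -0.5))
    v10 = tsi0 + spec.linear_span * a
    tsib = float(np.clip(rng.normal(*spec.tsib), 15.0, v10 - 2.0))
    amp = float(np.clip(rng.normal(*spec.amp), 5.0, 99.0 - tsib))
    td = float(np.clip(rng.normal(*spec.td), 2.0, 0.35 * spec.recovery_duration - 1.0))
    tau = float(np.clip(rng.normal(*spec.tau), 8.0, 150.0))
    return tsi0, a, tsib, amp, td, tau


def _power_time_constant(peak: float, mean: float, duration: float) -> float:
    """Decay constant T such that peak * T (1 - e^{-d/T}) / d equals the mean."""
    ratio = mean / peak
    ratio = min(max(ratio, 0.05), 0.98)

    def f(T):
        return T / duration * (1.0 - np.exp(-duration / T)) - ratio

    return brentq(f, 0.1, 5000.0)


def generate_session(
    spec: SyntheticSpec | None = None,
    condition: str | None = None,
    seed: int | None = None,
) -> tuple[TSITrace, PowerTrace, SessionProtocol, GroundTruth]:
    """Generate one synthetic session at 1 Hz.

    ``condition`` and ``seed`` override the spec's fields; identical
    (spec, condition, seed) triples give bit-identical output.
    """
    if spec is None:
        spec = default_spec(condition or "NOR")
    elif condition is not None and condition != spec.condition:
        spec = default_spec(condition, **{
            k: getattr(spec, k)
            for k in ("noise_sd", "drift_sd", "n_sprints", "sprint_duration",
                      "recovery_duration", "lead_in", "linear_span", "seed", "power_fatigue")
        })
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    sd, rd = spec.sprint_duration, spec.recovery_duration
    cycle = sd + rd
    starts = [spec.lead_in + i * cycle for i in range(spec.n_sprints)]
    protocol = SessionProtocol(
        sprint_starts=starts, sprint_duration=sd, recovery_duration=rd, condition=spec.condition
    )
    n_total = int(round(spec.lead_in + spec.n_sprints * cycle))
    t = np.arange(n_total, dtype=float)
    tsi = np.empty(n_total)

    params = [_draw_sprint_params(spec, rng) for _ in range(spec.n_sprints)]

    # session-level power base with per-sprint fatigue factor
    base_peak = rng.normal(*spec.peak_power)
    base_mean = rng.normal(*spec.mean_power)
    base_peak = max(base_peak, 150.0)
    base_mean = float(np.clip(base_mean, 0.3 * base_peak, 0.9 * base_peak))
    fatigue = 1.0 - spec.power_fatigue * np.arange(spec.n_sprints)
    fatigue = np.clip(fatigue + rng.normal(0.0, 0.01, spec.n_sprints), 0.4, None)
    fatigue[0] = 1.0  # sprint 1 is the best effort
    peak_i = base_peak * fatigue
    mean_i = base_mean * fatigue
    power = np.zeros(n_total)

    tsi[: int(spec.lead_in)] = params[0][0]
    for i, (tsi0, a, tsib, amp, td, tau) in enumerate(params):
        s0 = int(starts[i])
        u = np.arange(int(sd), dtype=float)
        lin = u <= spec.linear_span
        sprint = np.empty(int(sd))
        sprint[lin] = tsi0 + a * u[lin]
        v10 = tsi0 + a * spec.linear_span
        t_ease = (v10 - tsib) / (-a)  # slope-continuous at the linear/floor junction
        sprint[~lin] = tsib + (v10 - tsib) * np.exp(-(u[~lin] - spec.linear_span) / t_ease)
        tsi[s0 : s0 + int(sd)] = sprint
        ur = np.arange(int(rd), dtype=float)
        tsi[s0 + int(sd) : s0 + int(sd) + int(rd)] = predict_reoxy(ur, tsib, amp, td, tau)

        t_dec = _power_time_constant(peak_i[i], mean_i[i], sd)
        up = np.arange(int(sd) + 1, dtype=float)  # inclusive endpoint for the work integral
        power[s0 : s0 + int(sd) + 1] = peak_i[i] * np.exp(-up / t_dec)

    if spec.noise_sd > 0:
        tsi = tsi + rng.normal(0.0, spec.noise_sd, n_total)
    if spec.drift_sd > 0:
        tsi = tsi + np.cumsum(rng.normal(0.0, spec.drift_sd / 10.0, n_total))

    truth = GroundTruth(
        a=np.array([p[1] for p in params]),
        tsi0=np.array([p[0] for p in params]),
        tsib=np.array([p[2] for p in params]),
        amp_a=np.array([p[3] for p in params]),
        td=np.array([p[4] for p in params]),
        tau=np.array([p[5] for p in params]),
        a_prime=np.array([_a_prime(p[3], p[4], p[5], rd) for p in params]),
        mrt=np.array([_mrt(p[4], p[5]) for p in params]),
        peak_power=peak_i,
        mean_power=mean_i,
        condition=spec.condition,
        meta={"seed": seed, "noise_sd": spec.noise_sd, "drift_sd": spec.drift_sd},
    )
    tsi_trace = TSITrace(
        time=t, tsi=tsi, sampling_rate=1.0,
        meta={"synthetic": True, "condition": spec.condition, "seed": seed},
    )
    power_trace = PowerTrace(
        time=t.copy(), power=power, sampling_rate=1.0,
        meta={"synthetic": True, "condition": spec.condition, "seed": seed},
    )
    return tsi_trace, power_trace, protocol, truth
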