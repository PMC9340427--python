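"""Reading, validation and reduction of NIRS and crank-power traces.

The tissue saturation index (TSI) is the percentage of haemoglobin carrying
oxygen, computed from the oxygenated and total haemoglobin concentrations
measured by a continuous-wave NIRS probe::

    TSI = 100 * [O2Hb] / [tHb]

Raw probes acquire at 50 Hz; all downstream modelling works on a 1 Hz
series obtained by averaging every full second. This module owns the trace
containers, the TSI computation, the 50 Hz -> 1 Hz reduction, and
delimited-text I/O with provenance metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraceValidationError",
    "RawNirsTrace",
    "TSITrace",
    "PowerTrace",
    "compute_tsi",
    "reduce_to_1hz",
    "read_trace",
    "write_trace",
]


class TraceValidationError(ValueError):
    """Raised when a trace violates a structural invariant."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise TraceValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise TraceValidationError(f"{name} contains a non-finite value at index {bad}")
    return arr


def _check_rate(time: np.ndarray, sampling_rate: float, rtol: float = 0.01) -> None:
    if sampling_rate <= 0:
        raise TraceValidationError("sampling_rate must be positive")
    if time.size >= 2:
        dt = np.diff(time)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0])
            raise TraceValidationError(
                f"time must be strictly increasing; violation between samples {bad} and {bad + 1}"
            )
        med = float(np.median(dt))
        if abs(med - 1.0 / sampling_rate) > rtol / sampling_rate:
            raise TraceValidationError(
                f"sampling_rate={sampling_rate} Hz inconsistent with median time step {med:.6g} s"
            )


@dataclass
class RawNirsTrace:
    """Raw 2-channel NIRS trace: oxygenated and total haemoglobin, a.u."""

    time: np.ndarray
    o2hb: np.ndarray
    thb: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.o2hb = _as_float_array(self.o2hb, "o2hb")
        self.thb = _as_float_array(self.thb, "thb")
        if not (self.time.size == self.o2hb.size == self.thb.size):
            raise TraceValidationError("time, o2hb and thb must have equal lengths")
        _check_rate(self.time, self.sampling_rate)
        if np.any(self.thb <= 0):
            bad = int(np.flatnonzero(self.thb <= 0)[0])
            raise TraceValidationError(f"thb must be > 0; non-positive value at sample {bad}")
        if np.any(self.o2hb < 0):
            bad = int(np.flatnonzero(self.o2hb < 0)[0])
            raise TraceValidationError(f"o2hb must be >= 0; negative value at sample {bad}")
        n_over = int(np.sum(self.o2hb > self.thb))
        if n_over:
            self.meta.setdefault("n_o2hb_above_thb", n_over)
            warnings.warn(
                f"{n_over} samples have o2hb > thb (TSI > 100%); passed through unclipped",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.time.size

    def to_tsi(self) -> "TSITrace":
        """Element-wise TSI at the raw sampling rate."""
        tsi = compute_tsi(self.o2hb, self.thb)
        meta = dict(self.meta)
        meta["tsi_order"] = "computed sample-wise before any averaging"
        return TSITrace(time=self.time.copy(), tsi=tsi, sampling_rate=self.sampling_rate, meta=meta)


@dataclass
class TSITrace:
    """Tissue saturation index series on a uniform time grid (percent)."""

    time: np.ndarray
    tsi: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.tsi = _as_float_array(self.tsi, "tsi")
        if self.time.size != self.tsi.size:
            raise TraceValidationError("time and tsi must have equal lengths")
        _check_rate(self.time, self.sampling_rate)
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.ptp(dt) > 0.01 / self.sampling_rate:
                raise TraceValidationError("tsi time grid must be uniform")
        n_out = int(np.sum((self.tsi < 0) | (self.tsi > 100)))
        if n_out:
            # instrument noise can push the ratio outside [0, 100]; the
            # filter must see the raw signal, so values are flagged not clipped
            self.meta.setdefault("n_tsi_outside_0_100", n_out)

    def __len__(self) -> int:
        return self.time.size


@dataclass
class PowerTrace:
    """Crank power series in watts."""

    time: np.ndarray
    power: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.power = _as_float_array(self.power, "power")
        if self.time.size != self.power.size:
            raise TraceValidationError("time and power must have equal lengths")
        _check_rate(self.time, self.sampling_rate)
        if np.any(self.power < 0):
            bad = int(np.flatnonzero(self.power < 0)[0])
            raise TraceValidationError(f"power must be >= 0; negative value at sample {bad}")

    def __len__(self) -> int:
        return self.time.size


def compute_tsi(o2hb, thb):
    """Tissue saturation index, ``100 * o2hb / thb`` (percent).

    Scalar or element-wise on arrays. ``thb <= 0`` is an error naming the
    offending sample; ``o2hb > thb`` yields a value above 100 which is
    passed through with a warning rather than clipped.
    """
    o2hb_a = np.asarray(o2hb, dtype=float)
    thb_a = np.asarray(thb, dtype=float)
    if np.any(thb_a <= 0):
        bad = int(np.flatnonzero(np.atleast_1d(thb_a <= 0))[0])
        raise ValueError(f"thb must be > 0; non-positive value at sample {bad}")
    if np.any(o2hb_a < 0):
        bad = int(np.flatnonzero(np.atleast_1d(o2hb_a < 0))[0])
        raise ValueError(f"o2hb must be >= 0; negative value at sample {bad}")
    if np.any(o2hb_a > thb_a):
        n_over = int(np.sum(o2hb_a > thb_a))
        warnings.warn(f"{n_over} samples have o2hb > thb (TSI > 100%); not clipped", stacklevel=2)
    out = 100.0 * o2hb_a / thb_a
    if np.isscalar(o2hb) and np.isscalar(thb):
        return float(out)
    return out


def reduce_to_1hz(trace) -> TSITrace:
    """Average a high-rate trace into 1 s bins, yielding a 1 Hz TSI series.

    Each output sample is the arithmetic mean of the raw samples falling in
    the half-open bin ``[t, t+1)``; output time stamps are bin left edges.
    A trailing partial bin is discarded. ``RawNirsTrace`` input is converted
    to TSI sample-wise first, then averaged.
    """
    if isinstance(trace, RawNirsTrace):
        trace = trace.to_tsi()
    if not isinstance(trace, TSITrace):
        raise TypeError("reduce_to_1hz expects a RawNirsTrace or TSITrace")
    if len(trace) == 0:
        raise TraceValidationError("cannot reduce an empty trace")
    if trace.sampling_rate < 1.0:
        raise TraceValidationError("input sampling rate must be >= 1 Hz")
    n_per = int(round(trace.sampling_rate))
    n_bins = len(trace) // n_per
    if n_bins == 0:
        raise TraceValidationError("trace shorter than one second; nothing to average")
    binned = trace.tsi[: n_bins * n_per].reshape(n_bins, n_per).mean(axis=1)
    t0 = trace.time[0]
    meta = dict(trace.meta)
    meta["reduced_from_hz"] = trace.sampling_rate
    meta["dropped_trailing_samples"] = len(trace) - n_bins * n_per
    return TSITrace(time=t0 + np.arange(n_bins, dtype=float), tsi=binned, sampling_rate=1.0, meta=meta)


_FORMATS = {
    "o2hb_thb": ("time", "o2hb", "thb"),
    "tsi": ("time", "tsi"),
    "power": ("time", "power"),
}


def read_trace(path, format: str = "tsi", sampling_rate: float | None = None, columns: dict | None = None):
    """Read a delimited-text trace (CSV/TSV with header).

    Parameters
    ----------
    format : {"o2hb_thb", "tsi", "power"}
        Which trace container to build.
    sampling_rate : float, optional
        Inferred from the median time step when omitted.
    columns : dict, optional
        Mapping from canonical names (``time``, ``o2hb`` ...) to the file's
        header names.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_FORMATS)}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    colmap = {name: (columns or {}).get(name, name) for name in _FORMATS[format]}
    data = {}
    for canonical, col in colmap.items():
        if col not in df.columns:
            raise TraceValidationError(f"missing column {col!r} in {path.name}")
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise TraceValidationError(f"non-numeric value in column {col!r} at line {row} of {path.name}")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise TraceValidationError(f"empty value in column {col!r} at line {row} of {path.name}")
        data[canonical] = numeric.to_numpy()
    time = data["time"]
    if np.any(np.diff(time) == 0):
        raise TraceValidationError(f"duplicated timestamp in {path.name}")
    if sampling_rate is None:
        if time.size < 2:
            raise TraceValidationError("cannot infer sampling rate from a single sample")
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    meta = {"source": str(path), "columns": colmap, "format": format}
    if format == "o2hb_thb":
        return RawNirsTrace(time, data["o2hb"], data["thb"], sampling_rate, meta)
    if format == "tsi":
        return TSITrace(time, data["tsi"], sampling_rate, meta)
    return PowerTrace(time, data["power"], sampling_rate, meta)


def write_trace(trace, path) -> Path:
    """Write a trace as CSV with 6 significant digits (round-trip stable)."""
    path = Path(path)
    if isinstance(trace, RawNirsTrace):
        df = pd.DataFrame({"time": trace.time, "o2hb": trace.o2hb, "thb": trace.thb})
    elif isinstance(trace, TSITrace):
        df = pd.DataFrame({"time": trace.time, "tsi": trace.tsi})
    elif isinstance(trace, PowerTrace):
        df = pd.DataFrame({"time": trace.time, "power": trace.power})
    else:
        raise TypeError(f"cannot write object of type {type(trace).__name__}")
    df.to_csv(path, index=False, float_format="%.6g")
    return path
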