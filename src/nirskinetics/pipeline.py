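"""Pipeline orchestration and group summary tables.

``run_pipeline`` chains ingest -> (optional) low-pass filter -> segmentation
-> linear deoxygenation fits -> exponential reoxygenation fits -> sprint
performance, writes every intermediate as CSV and records a machine-readable
provenance file. ``summarize`` aggregates fit collections into mean ± SD
tables (sample SD, n-1 denominator; a single fit reports SD 0) by condition
or by sprint. Only exponential fits passing the strict R^2 > 0.80 inclusion
rule enter the reoxygenation summaries; exclusion counts are logged.

Inferential statistics (mixed models, post hoc contrasts, correlations) are
deliberately not implemented here: ``fits_to_frame`` exports tidy
long-format tables for external statistical tools.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deoxy import delta_tsi, fit_linear_deoxy
from .io import read_trace, reduce_to_1hz, write_trace
from .performance import SprintPerformance, power_decrease, sprint_metrics
from .preprocess import SessionProtocol, butterworth_lowpass, segment_session
from .reoxy import fit_reoxy
from .synthetic import SyntheticSpec, default_spec, generate_session

__all__ = ["PipelineError", "analyze_session", "fits_to_frame", "summarize", "run_pipeline"]

log = logging.getLogger(__name__)

_DEOXY_PARAMS = ["a", "tsi0", "a_adj", "delta_tsi", "r2"]
_REOXY_PARAMS = ["a_prime", "td", "tau", "mrt", "tsib", "amp_a", "r2", "adj_r2"]
_PERF_PARAMS = ["peak_power", "mean_power", "total_work"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def fits_to_frame(fits) -> pd.DataFrame:
    """Tidy long-format export of a list of fit/performance dataclasses."""
    return pd.DataFrame([dataclasses.asdict(f) for f in fits])


def analyze_session(tsi_trace, protocol: SessionProtocol, power_trace=None,
                    cutoff: float | None = 0.1, order: int = 2, zero_phase: bool = True,
                    t_end: float | None = None, reoxy_params: dict | None = None):
    """Run filter -> segment -> fits on one session; returns a dict of results.

    ``cutoff=None`` skips the smoothing stage (useful for noise-free
    signals, where the low-pass would only distort the kinetics).
    """
    if t_end is None:
        t_end = protocol.recovery_duration
    filtered = tsi_trace if cutoff is None else butterworth_lowpass(tsi_trace, cutoff, order, zero_phase)
    segments = segment_session(filtered, protocol)
    by_kind = {k: [s for s in segments if s.kind == k] for k in ("deoxy_window", "sprint", "recovery")}

    perf = []
    if power_trace is not None:
        for i, start in enumerate(protocol.sprint_starts, start=1):
            perf.append(sprint_metrics(power_trace, start, protocol.sprint_duration, i, protocol.condition))

    deoxy_fits = []
    for win, spr in zip(by_kind["deoxy_window"], by_kind["sprint"]):
        work = perf[win.sprint_index - 1].total_work if perf else None
        fit = fit_linear_deoxy(win, total_work=work)
        fit.delta_tsi = delta_tsi(spr)
        deoxy_fits.append(fit)

    reoxy_fits = [fit_reoxy(rec, t_end=t_end, **(reoxy_params or {})) for rec in by_kind["recovery"]]

    out = {
        "filtered": filtered,
        "segments": segments,
        "deoxy_fits": deoxy_fits,
        "reoxy_fits": reoxy_fits,
        "performance": perf,
        "power_decrease": power_decrease([p.mean_power for p in perf]) if perf else None,
    }
    n_inc = sum(f.included for f in reoxy_fits)
    log.info("reoxygenation inclusion: %d/%d fits with R^2 > 0.80", n_inc, len(reoxy_fits))
    return out


def summarize(deoxy_fits=None, reoxy_fits=None, performance=None, by: str = "condition") -> pd.DataFrame:
    """Mean ± SD summary table over fit collections.

    Returns a tidy frame with columns ``parameter, group, mean, sd, n``;
    ``by`` groups over ``condition`` or ``sprint`` (sprint_index). Reoxy
    rows use only fits with ``included=True``; cells left empty (NaN, n=0)
    trigger a warning.
    """
    if by not in ("condition", "sprint"):
        raise ValueError("by must be 'condition' or 'sprint'")
    key = "condition" if by == "condition" else "sprint_index"
    blocks = []
    all_groups: set = set()
    if deoxy_fits:
        df = fits_to_frame(deoxy_fits)
        all_groups.update(df[key].unique())
        blocks.append(("deoxy", df, [p for p in _DEOXY_PARAMS if p in df.columns]))
    if reoxy_fits:
        df = fits_to_frame(reoxy_fits)
        n_total = len(df)
        all_groups.update(df[key].unique())
        df = df[df["included"]]
        log.info("summary uses %d/%d exponential fits (R^2 > 0.80)", len(df), n_total)
        blocks.append(("reoxy", df, [p for p in _REOXY_PARAMS if p in df.columns]))
    if performance:
        df = fits_to_frame(performance)
        all_groups.update(df[key].unique())
        blocks.append(("performance", df, [p for p in _PERF_PARAMS if p in df.columns]))
    if not blocks:
        raise ValueError("no fit collections supplied")

    rows = []
    groups = sorted(all_groups)
    for model, df, params in blocks:
        for param in params:
            for g in groups:
                vals = df.loc[df[key] == g, param].dropna().to_numpy(dtype=float)
                if vals.size == 0:
                    warnings.warn(f"no included fits for {param!r} in group {g!r}; cell left empty", stacklevel=2)
                    rows.append({"model": model, "parameter": param, "group": g, "mean": np.nan, "sd": np.nan, "n": 0})
                else:
                    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
                    rows.append({"model": model, "parameter": param, "group": g, "mean": float(vals.mean()), "sd": sd, "n": int(vals.size)})
    return pd.DataFrame(rows)


def format_summary(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy summary into a 'mean ± sd (n)' display table."""
    disp = tidy.copy()
    disp["cell"] = [
        "" if n == 0 else f"{m:.2f} ± {s:.2f} (n={n})"
        for m, s, n in zip(disp["mean"], disp["sd"], disp["n"])
    ]
    return disp.pivot(index=["model", "parameter"], columns="group", values="cell")


def _load_protocol(obj) -> SessionProtocol:
    if isinstance(obj, SessionProtocol):
        return obj
    if isinstance(obj, (str, Path)):
        with open(obj) as fh:
            obj = yaml.safe_load(fh)
    return SessionProtocol(**obj)


def run_pipeline(config, output_dir=None) -> dict:
    """Execute the full pipeline from a config mapping or YAML path.

    Config keys: ``simulate`` (condition/seed/spec overrides) or ``inputs``
    (tsi/nirs/power file paths + ``protocol``); optional ``filter``
    (cutoff/order/zero_phase; cutoff null disables), ``fit`` (t_end, extra
    reoxygenation options), ``output_dir``. Outputs are a pure function of
    (inputs, config, seed).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    out_dir = Path(output_dir or config.get("output_dir", "nirs_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        truth = None
        if "simulate" in config:
            sim = dict(config["simulate"])
            condition = sim.pop("condition", "NOR")
            seed = sim.pop("seed", 0)
            spec_over = {k: v for k, v in sim.items() if k in SyntheticSpec.__dataclass_fields__}
            spec = default_spec(condition, **spec_over)
            tsi_trace, power_trace, protocol, truth = generate_session(spec, seed=seed)
        elif "inputs" in config:
            inputs = config["inputs"]
            if "protocol" not in inputs:
                raise PipelineError("config inputs missing required field 'protocol'")
            protocol = _load_protocol(inputs["protocol"])
            if "tsi" in inputs:
                trace = read_trace(inputs["tsi"], format="tsi", sampling_rate=inputs.get("rate"))
            elif "nirs" in inputs:
                trace = read_trace(inputs["nirs"], format="o2hb_thb", sampling_rate=inputs.get("rate"))
            else:
                raise PipelineError("config inputs must name a 'tsi' or 'nirs' file")
            tsi_trace = reduce_to_1hz(trace) if trace.sampling_rate > 1.001 else (
                trace if hasattr(trace, "tsi") else trace.to_tsi()
            )
            power_trace = read_trace(inputs["power"], format="power") if "power" in inputs else None
        else:
            raise PipelineError("config must contain a 'simulate' or 'inputs' section")

        stage = "preprocess+fit"
        filt = dict(config.get("filter", {}))
        fit_cfg = dict(config.get("fit", {}))
        res = analyze_session(
            tsi_trace, protocol, power_trace,
            cutoff=filt.get("cutoff", 0.1), order=filt.get("order", 2),
            zero_phase=filt.get("zero_phase", True),
            t_end=fit_cfg.pop("t_end", None), reoxy_params=fit_cfg or None,
        )

        stage = "write"
        write_trace(res["filtered"], out_dir / "tsi_filtered.csv")
        deoxy_df = fits_to_frame(res["deoxy_fits"])
        reoxy_df = fits_to_frame(res["reoxy_fits"])
        deoxy_df.to_csv(out_dir / "deoxy_fits.csv", index=False, float_format="%.6g")
        reoxy_df.to_csv(out_dir / "reoxy_fits.csv", index=False, float_format="%.6g")
        if res["performance"]:
            perf_df = fits_to_frame(res["performance"])
            perf_df["power_decrease"] = res["power_decrease"]
            perf_df.to_csv(out_dir / "performance.csv", index=False, float_format="%.6g")
        tidy = summarize(res["deoxy_fits"], res["reoxy_fits"], res["performance"] or None, by="sprint")
        tidy.to_csv(out_dir / "summary_by_sprint.csv", index=False, float_format="%.6g")
        if truth is not None:
            truth.to_frame().to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.6g")

        provenance = {
            "package": "nirskinetics",
            "version": __version__,
            "numpy": np.__version__,
            "config": _jsonable(config),
            "condition": protocol.condition,
            "n_sprints": protocol.n_sprints,
            "n_reoxy_included": int(sum(f.included for f in res["reoxy_fits"])),
            "n_reoxy_total": len(res["reoxy_fits"]),
        }
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    res["output_dir"] = out_dir
    res["protocol"] = protocol
    res["ground_truth"] = truth
    return res


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
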