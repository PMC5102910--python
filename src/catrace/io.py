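"""Recording ingestion, per-trace pipeline orchestration, and result output.

Input layout: first column = time, every further column = one region of
interest (ROI); a header row is auto-detected.  Both ``.xlsx`` (first
worksheet) and ``.csv`` are accepted.  Each ROI is processed independently —
a failure in one trace yields a flagged result row and never aborts the
batch.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .drift import (Delimitation, DriftParams, delimit, fit_drift_initial,
                    fit_drift_weighted, global_drift)
from .mpr import (DeviationSet, MPRMetrics, bias_weights, cluster_coherent,
                  find_deviations, mpr_metrics, refit_response_weighted,
                  reliability_weights)
from .transient import (ActivationFit, ResponseParams, TRMetrics, detect_transient,
                        extract_tr_metrics, fit_activation, fit_response,
                        global_response)
from .tv import TVState, tv_iterate


@dataclass
class Trace:
    """One recording: strictly increasing times (s) and signal values (a.u.)."""

    trace_id: str
    times: np.ndarray
    values: np.ndarray
    stimulus_time: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError(f"{self.trace_id}: times/values length mismatch")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.trace_id}: times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class TraceReport:
    trace_id: str
    detected: bool = False
    criteria: tuple[bool, bool, bool] = (False, False, False)
    tr: TRMetrics = field(default_factory=TRMetrics)
    mpr_all: MPRMetrics | None = None
    mpr_coherent: MPRMetrics | None = None
    residual_rms: float = np.nan
    n_spikes: int = 0
    error: str | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_recordings(path: str | Path, config: PipelineConfig | None = None) -> list[Trace]:
    """Read a spreadsheet/CSV of traces: time column followed by ROI columns.

    Rows whose cell is non-numeric are dropped per column (together with the
    matching time stamps), so ROIs of different usable length coexist.
    """
    cfg = config or PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, sheet_name=0, header=None)
    else:
        raw = pd.read_csv(path, header=None)
    if raw.shape[1] < 2:
        raise ValueError("need at least a time column and one ROI column")

    # header row detection: first row entirely convertible -> no header
    first = pd.to_numeric(raw.iloc[0], errors="coerce")
    has_header = first.isna().any()
    names = [str(v) for v in raw.iloc[0]] if has_header else \
        ["time"] + [f"roi{i}" for i in range(1, raw.shape[1])]
    body = raw.iloc[1:] if has_header else raw
    num = body.apply(pd.to_numeric, errors="coerce")

    t_all = num.iloc[:, 0].to_numpy(dtype=float) * cfg.time_scale
    traces = []
    for c in range(1, num.shape[1]):
        v = num.iloc[:, c].to_numpy(dtype=float)
        ok = np.isfinite(t_all) & np.isfinite(v)
        t = t_all[ok]
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"column {names[c]}: time column not strictly increasing")
        traces.append(Trace(trace_id=names[c], times=t, values=v[ok]))
    return traces


def write_recordings(traces: list[Trace], path: str | Path) -> None:
    """Write traces in the same layout :func:`read_recordings` consumes.

    All traces must share one time base; format follows the file suffix.
    """
    path = Path(path)
    t0 = traces[0].times
    data = {"time": t0}
    for tr in traces:
        if tr.times.size != t0.size or not np.allclose(tr.times, t0):
            raise ValueError("all traces must share one time base for writing")
        data[tr.trace_id] = tr.values
    df = pd.DataFrame(data)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-trace pipeline
# ---------------------------------------------------------------------------

@dataclass
class TraceResult:
    """Report plus the fitted objects, for plotting and downstream analysis."""

    report: TraceReport
    tvstate: TVState | None = None
    delim: Delimitation | None = None
    drift: DriftParams | None = None
    response: ResponseParams | None = None
    deviations: DeviationSet | None = None


def characterize_trace(trace: Trace, config: PipelineConfig | None = None) -> TraceResult:
    """Run the full decomposition on one trace.

    Order of stages: TV derivative estimation and spike removal; epoch
    delimitation; drift fit (plain, then derivative-weighted); joint
    activation+drift fit; three-way detection; full response fit; deviation
    analysis with reliability-weighted refit and coherence clustering.
    """
    cfg = config or PipelineConfig()
    t, F = trace.times, trace.values
    if cfg.trim_before is not None:
        keep = t >= cfg.trim_before
        t, F = t[keep], F[keep]
    report = TraceReport(trace_id=trace.trace_id)
    if t.size < 20:
        report.error = "trace too short (N < 20)"
        return TraceResult(report=report)
    if not np.all(np.isfinite(F)):
        report.error = "non-finite values after ingestion"
        return TraceResult(report=report)

    tvstate = tv_iterate(F, t, cfg)
    report.n_spikes = int(tvstate.spike_mask.sum())
    report.flags += tvstate.flags
    if "constant_trace" in tvstate.flags:
        report.error = "constant trace"
        return TraceResult(report=report, tvstate=tvstate)

    delim = delimit(t, tvstate)
    report.flags += delim.flags

    theta0 = fit_drift_initial(t, F, delim, tvstate.clean_mask, cfg,
                               two_components=delim.has_activation)
    theta_w, w = fit_drift_weighted(t, F, tvstate, delim, theta0, cfg)
    report.flags += theta_w.flags

    act_fit: ActivationFit | None = None
    if delim.has_activation:
        act_fit = fit_activation(t, F, tvstate, delim, theta_w, w, cfg)
        report.flags += act_fit.flags
        detected, crits, best_drift = detect_transient(
            t, F, tvstate, delim, theta_w, act_fit.drift, w, cfg)
    else:
        detected, crits, best_drift = False, (False, False, True), theta_w
    report.detected = detected
    report.criteria = crits

    response: ResponseParams | None = None
    dev: DeviationSet | None = None
    if detected:
        response = fit_response(t, F, tvstate, delim, act_fit, cfg)
        report.flags += response.flags
        dev = find_deviations(t, tvstate, response, best_drift, cfg)
        if dev.n_tilde > 2:
            o_p, o_t = bias_weights(dev)
            omega = reliability_weights(t, tvstate, response, dev, o_p, o_t)
            response = refit_response_weighted(t, F, tvstate, delim, act_fit, omega, cfg)
            dev = find_deviations(t, tvstate, response, best_drift, cfg)
        report.tr = extract_tr_metrics(t, F, tvstate, response, cfg)
        model = np.atleast_1d(global_response(t, response))
        report.residual_rms = float(np.sqrt(np.mean((F[tvstate.clean_mask] -
                                                     model[tvstate.clean_mask]) ** 2)))
    else:
        dev = find_deviations(t, tvstate, None, best_drift, cfg)
        model = global_drift(t, best_drift)
        report.residual_rms = float(np.sqrt(np.mean((F[tvstate.clean_mask] -
                                                     model[tvstate.clean_mask]) ** 2)))

    if dev is not None and dev.n_tilde > 2:
        dev = cluster_coherent(dev, seed=cfg.seed, config=cfg)
        report.mpr_all = mpr_metrics(dev, "all")
        report.mpr_coherent = mpr_metrics(dev, "coherent")

    return TraceResult(report=report, tvstate=tvstate, delim=delim,
                       drift=best_drift, response=response, deviations=dev)


def characterize_document(
    path: str | Path,
    config: PipelineConfig | None = None,
    plots_dir: str | Path | None = None,
) -> list[TraceResult]:
    """Read a recordings file and characterize every ROI column.

    Per-trace failures are captured as flagged error rows; the batch always
    completes.
    """
    cfg = config or PipelineConfig()
    traces = read_recordings(path, cfg)
    results = []
    for trace in traces:
        try:
            res = characterize_trace(trace, cfg)
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            res = TraceResult(report=TraceReport(trace_id=trace.trace_id,
                                                 error=f"{type(exc).__name__}: {exc}"))
        results.append(res)
        if plots_dir is not None and res.tvstate is not None:
            try:
                plot_trace(trace, res, Path(plots_dir) / f"{trace.trace_id}.png", cfg)
            except Exception:
                res.report.flags.append("plot_failed")
    return results


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_TR_FIELDS = ("t_onset", "t_10_90", "amplitude", "auc", "fwhm", "rho", "tau_decay")
_MPR_FIELDS = ("n_osc", "magnitude_E", "period_T", "sigma_T",
               "persistence_l_osc", "duty_cycle")


def reports_to_frame(results: list[TraceResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        rep = res.report
        row: dict = {"trace_id": rep.trace_id, "detected": rep.detected,
                     "error": rep.error or ""}
        for f in _TR_FIELDS:
            row[f] = getattr(rep.tr, f) if rep.detected else np.nan
        for prefix, m in (("mpr_all", rep.mpr_all), ("mpr_coh", rep.mpr_coherent)):
            for f in _MPR_FIELDS:
                row[f"{prefix}_{f}"] = getattr(m, f) if m is not None else np.nan
        row["n_spikes"] = rep.n_spikes
        row["residual_rms"] = rep.residual_rms
        row["flags"] = ";".join(rep.flags)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: list[TraceResult], csv_path: str | Path,
                  json_path: str | Path | None = None) -> pd.DataFrame:
    """Write the per-trace results table as CSV (full precision) and JSON."""
    df = reports_to_frame(results)
    # default float formatting = shortest round-trippable repr
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = []
        for res in results:
            d = dataclasses.asdict(res.report)
            payload.append(_jsonable(d))
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def plot_trace(trace: Trace, res: TraceResult, out_path: str | Path,
               config: PipelineConfig | None = None) -> None:
    """Diagnostic overlay: data, spikes, TV estimate, drift, fitted model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t, F = trace.times, trace.values
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(t, F, ".", color="0.7", ms=3, label="data")
    if res.tvstate is not None:
        ax.plot(t, res.tvstate.au, "-", color="tab:blue", lw=1, label="TV estimate")
        sp = res.tvstate.spike_idx
        if sp.size:
            ax.plot(t[sp], F[sp], "x", color="tab:red", label="spikes")
    if res.drift is not None:
        ax.plot(t, global_drift(t, res.drift), "--", color="tab:green", label="drift")
    if res.response is not None:
        ax.plot(t, np.atleast_1d(global_response(t, res.response)), "-",
                color="tab:orange", lw=1.5, label="fitted model")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("signal (a.u.)")
    ax.set_title(f"{trace.trace_id} (detected={res.report.detected})")
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
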