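"""Named end-to-end scenarios tying the model, stimuli and metrics together.

The scenario catalog is data (``data/scenarios.yaml``); each entry names a
protocol kind and its parameters.  ``run_scenario`` executes one entry and
returns traces plus a flat metrics dictionary; ``report`` collates metrics
against the shipped thresholds file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .config import (d2_from_dict, load_raw_config, load_scenario_catalog,
                     load_thresholds, model_from_dict)
from .metrics import phase_lag, rate_histogram, undershoot
from .simulator import (ModelConfig, VoltageTrace, apply_pharmacology,
                        calibrate_resting_potential, resting_potential,
                        simulate_current_clamp, simulate_voltage_steps)
from .stimuli import (D2Spec, StimulusWaveform, compose_scenario, d2_current,
                      negative_undershoot_mimic, sine_current,
                      trapezoid_current)
from .synthetic import RecordingSpec, generate_recording

__all__ = ["ScenarioResult", "run_scenario", "report", "scenario_names"]


@dataclass
class ScenarioResult:
    """Outputs of one scenario run (reproducible from config + seed)."""

    name: str
    params: Dict[str, Any]
    metrics: Dict[str, float]
    traces: Dict[str, VoltageTrace] = field(default_factory=dict)
    seed: Optional[int] = None
    version: str = __version__

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, trace in self.traces.items():
            trace.write_text(out / f"{self.name}_{label}_trace.tsv")
        with open(out / f"{self.name}_metrics.json", "w") as fh:
            json.dump(self.metrics, fh, indent=2)
        manifest = {
            "scenario": self.name,
            "params": self.params,
            "seed": self.seed,
            "version": self.version,
            "metrics_file": f"{self.name}_metrics.json",
        }
        with open(out / f"{self.name}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# small trace-metric helpers


def _trough(trace: VoltageTrace, rmp: float, t0: float,
            t1: Optional[float] = None) -> Tuple[float, float]:
    """(depth below rmp, time of minimum) within [t0, t1]."""
    sel = trace.time >= t0
    if t1 is not None:
        sel &= trace.time <= t1
    v = trace.v[sel]
    t = trace.time[sel]
    i = int(np.argmin(v))
    return max(0.0, rmp - float(v[i])), float(t[i])


def _below_rmp_duration(trace: VoltageTrace, rmp: float, t0: float, t1: float,
                        margin: float = 0.1) -> float:
    sel = (trace.time >= t0) & (trace.time <= t1)
    below = trace.time[sel][trace.v[sel] < rmp - margin]
    return float(below[-1] - below[0]) if below.size else 0.0


def _calibrated(config: ModelConfig) -> ModelConfig:
    return replace(config, leak_e=calibrate_resting_potential(config, verify=False))


def _variant_config(base: ModelConfig, channel_names: Sequence[str]) -> ModelConfig:
    return _calibrated(base.with_only(list(channel_names)))


def _trapezoid(p: Dict[str, Any], dt: float) -> StimulusWaveform:
    return trapezoid_current(p["peak_pA"], p["ramp_up_ms"], p["plateau_ms"],
                             p["ramp_down_ms"], dt=dt, tail=p.get("tail_ms", 0.0))


def _pad(total_ms: float, dt: float) -> StimulusWaveform:
    """Zero-current placeholder extending a composite to ``total_ms``."""
    n = int(round(total_ms / dt))
    return StimulusWaveform(np.arange(n + 1) * dt, np.zeros(n + 1))


# ---------------------------------------------------------------------------
# scenario kinds


def _run_vclamp(model: ModelConfig, p, d2, rec, seed):
    res = simulate_voltage_steps(model, p["holding_mV"], p["step_mV"],
                                 p["n_steps"], p["step_dur_ms"])
    metrics: Dict[str, float] = {}
    for name, fam in res.currents.items():
        top = fam[-1]
        peak = float(np.max(np.abs(top)))
        final = float(abs(top[-1]))
        metrics[f"{name}_sag_fraction"] = 1.0 - final / peak if peak > 0 else 0.0
    # rename to the metric names used in the thresholds file
    metrics["a_inactivation_fraction"] = metrics.pop("a_sag_fraction", 0.0)
    return metrics, {}


def _run_trapezoid_variants(model: ModelConfig, p, d2, rec, seed):
    stim = _trapezoid(p, model.dt)
    metrics: Dict[str, float] = {}
    traces: Dict[str, VoltageTrace] = {}
    for label, names in p["variants"].items():
        cfg = _variant_config(model, names)
        trace = simulate_current_clamp(cfg, stim, record_currents=False)
        us = undershoot(trace, cfg.target_rmp, stim.annotations)
        metrics[f"undershoot_mV_{label}"] = us.trough_depth
        metrics[f"overshoot_mV_{label}"] = us.peak_height
        traces[label] = trace
    return metrics, traces


def _run_current_lag(model: ModelConfig, p, d2, rec, seed):
    stim = _trapezoid(p, model.dt)
    trace = simulate_current_clamp(model, stim, record_currents=True)
    t_input = float(stim.time[int(np.argmax(stim.current))])
    ikr = trace.currents["kr"]
    t_kr = float(trace.time[int(np.argmax(ikr))])
    metrics = {"t_input_peak_ms": t_input, "t_kr_peak_ms": t_kr,
               "kr_lag_ms": t_kr - t_input}
    return metrics, {"full": trace}


def _run_rmp_dependence(model: ModelConfig, p, d2, rec, seed):
    stim = _trapezoid(p, model.dt)
    metrics: Dict[str, float] = {}
    traces: Dict[str, VoltageTrace] = {}
    depths: Dict[str, float] = {}
    for scen in p["variants"]:
        cfg = apply_pharmacology(model, scen)
        rmp = resting_potential(cfg)
        trace = simulate_current_clamp(cfg, stim, record_currents=False)
        us = undershoot(trace, rmp, stim.annotations)
        metrics[f"undershoot_mV_{scen}"] = us.trough_depth
        metrics[f"rmp_mV_{scen}"] = rmp
        depths[scen] = us.trough_depth
        traces[scen] = trace
    control = depths.get("control", 0.0)
    if control > 0:
        metrics["undershoot_loss_fraction"] = 1.0 - depths.get("zd7288", 0.0) / control
        metrics["undershoot_restored_fraction"] = (
            depths.get("zd7288_restored", 0.0) / control)
    return metrics, traces


def _run_sine_family(model: ModelConfig, p, d2, rec, seed):
    metrics: Dict[str, float] = {}
    traces: Dict[str, VoltageTrace] = {}
    troughs: List[float] = []
    latencies: List[float] = []
    for amp in p["amplitudes_pA"]:
        stim = sine_current(amp, p["freq_hz"], p["duration_ms"], dt=model.dt,
                            tail=p["tail_ms"])
        trace = simulate_current_clamp(model, stim, record_currents=False)
        us = undershoot(trace, model.target_rmp,
                        {"sine": (0.0, p["duration_ms"])})
        label = f"{int(amp)}"
        metrics[f"trough_mV_{label}"] = us.trough_depth
        metrics[f"trough_latency_ms_{label}"] = us.trough_latency
        troughs.append(us.trough_depth)
        latencies.append(us.trough_latency)
        traces[label] = trace
    metrics["trough_monotone"] = float(all(b > a for a, b in zip(troughs, troughs[1:])))
    metrics["latency_range_ms"] = float(max(latencies) - min(latencies))
    return metrics, traces


def _run_d2_summation(model: ModelConfig, p, d2: D2Spec, rec, seed):
    d2 = replace(d2, **{k.removesuffix("_ms").replace("peak_pA", "peak"): v
                        for k, v in p.get("d2_override", {}).items()})
    bump = _trapezoid({**p["bump"], "tail_ms": p["tail_ms"]}, model.dt)
    wave_d2 = d2_current(d2, dt=model.dt)
    pad = _pad(bump.duration, model.dt)
    variants = {
        "ikr_only": bump,
        "d2_only": compose_scenario([(wave_d2, 0.0, 1.0), (pad, 0.0, 0.0)]),
        "combined": compose_scenario([(bump, 0.0, 1.0), (wave_d2, 0.0, 1.0)]),
    }
    rmp = model.target_rmp
    offset = (p["bump"]["ramp_up_ms"] + p["bump"]["plateau_ms"]
              + p["bump"]["ramp_down_ms"])
    metrics: Dict[str, float] = {}
    traces: Dict[str, VoltageTrace] = {}
    for label, stim in variants.items():
        trace = simulate_current_clamp(model, stim, record_currents=False)
        t0 = offset if label != "d2_only" else 0.0
        depth, _ = _trough(trace, rmp, t0)
        metrics[f"trough_mV_{label}"] = depth
        metrics[f"below_rmp_ms_{label}"] = _below_rmp_duration(
            trace, rmp, t0, float(trace.time[-1]))
        traces[label] = trace
    metrics["trough_deepening_mV"] = (metrics["trough_mV_combined"]
                                      - metrics["trough_mV_ikr_only"])
    return metrics, traces


def _d2_timing_parts(model, p, d2, scale: float = 1.0, rebound: bool = True,
                     with_d2: bool = True):
    parts = [(_trapezoid(p["bump"], model.dt), 0.0, scale)]
    if rebound:
        parts.append((_trapezoid(p["rebound"], model.dt),
                      p["rebound"]["onset_ms"], scale))
    if with_d2:
        parts.append((d2_current(d2, dt=model.dt), p["d2_shift_ms"], 1.0))
    parts.append((_pad(p["total_ms"], model.dt), 0.0, 0.0))
    return compose_scenario(parts)


def _run_d2_timing(model: ModelConfig, p, d2: D2Spec, rec, seed):
    rmp = model.target_rmp
    t0, t1 = p["trough_window_ms"]
    r0, r1 = p["rebound_window_ms"]
    variants = {
        "no_d2": _d2_timing_parts(model, p, d2, with_d2=False),
        "with_d2": _d2_timing_parts(model, p, d2),
        "d2_no_rebound": _d2_timing_parts(model, p, d2, rebound=False),
        "input_only_no_rebound": _d2_timing_parts(model, p, d2, rebound=False,
                                                  with_d2=False),
    }
    metrics: Dict[str, float] = {}
    traces: Dict[str, VoltageTrace] = {}
    for label, stim in variants.items():
        trace = simulate_current_clamp(model, stim, record_currents=False)
        depth, _ = _trough(trace, rmp, t0, t1)
        metrics[f"trough_mV_{label}"] = depth
        sel = (trace.time >= r0) & (trace.time <= r1)
        metrics[f"rebound_mV_{label}"] = float(trace.v[sel].max()) - rmp
        metrics[f"below_rmp_ms_{label}"] = _below_rmp_duration(
            trace, rmp, t0, p["total_ms"])
        traces[label] = trace
    ref = metrics["trough_mV_no_d2"]
    metrics["trough_change_frac"] = (
        abs(metrics["trough_mV_with_d2"] - ref) / ref if ref > 0 else 0.0)
    metrics["rebound_reduction_mV"] = (metrics["rebound_mV_no_d2"]
                                       - metrics["rebound_mV_with_d2"])
    return metrics, traces


def _run_learning_scaling(model: ModelConfig, p, d2: D2Spec, rec, seed):
    rmp = model.target_rmp
    t0, t1 = p["trough_window_ms"]
    metrics: Dict[str, float] = {}
    traces: Dict[str, VoltageTrace] = {}
    depths: List[float] = []
    for scale in p["excitatory_scales"]:
        stim = _d2_timing_parts(model, p, d2, scale=scale)
        trace = simulate_current_clamp(model, stim, record_currents=False)
        depth, _ = _trough(trace, rmp, t0, t1)
        label = f"{int(round(scale * 100))}"
        metrics[f"trough_mV_{label}"] = depth
        depths.append(depth)
        traces[label] = trace
    metrics["trough_monotone"] = float(all(b > a for a, b in zip(depths, depths[1:])))
    return metrics, traces


def _run_undershoot_mimic(model: ModelConfig, p, d2, rec, seed):
    stim = negative_undershoot_mimic(p["r_in_MOhm"], p["v_target_mV"],
                                     dt=model.dt, tail=p["tail_ms"])
    trace = simulate_current_clamp(model, stim, record_currents=False)
    metrics = {
        "amplitude_pA": float(stim.current.min()),
        "hyperpol_mV": max(0.0, model.target_rmp - float(trace.v.min())),
    }
    return metrics, {"mimic": trace}


def _run_small_withdrawal(model: ModelConfig, p, d2, rec, seed):
    stim = sine_current(p["amplitude_pA"], p["freq_hz"], p["duration_ms"],
                        dt=model.dt, tail=p["tail_ms"])
    trace = simulate_current_clamp(model, stim, record_currents=False)
    us = undershoot(trace, model.target_rmp, {"sine": (0.0, p["duration_ms"])})
    return {"undershoot_mV": us.trough_depth,
            "peak_mV": us.peak_height}, {"withdrawal": trace}


def _run_invivo_phase(model: ModelConfig, p, d2, rec: RecordingSpec, seed):
    if seed is not None:
        rec = replace(rec, seed=int(seed))
    recording = generate_recording(rec)
    window = (0.0, rec.duration_ms)
    hist_chi = rate_histogram(recording.trains["chi"], bin=p["bin_ms"],
                              window=window)
    hist_spn = rate_histogram(recording.trains["spn"], bin=p["bin_ms"],
                              window=window)
    lag = phase_lag(hist_chi, hist_spn, rec.slow_freq)
    metrics = {
        "spn_chi_lag_deg": lag,
        "chi_mean_rate_hz": float(np.mean(hist_chi.rate)),
        "spn_mean_rate_hz": float(np.mean(hist_spn.rate)),
        "n_sweeps": float(rec.n_sweeps),
    }
    return metrics, {}


_KINDS: Dict[str, Callable] = {
    "vclamp": _run_vclamp,
    "trapezoid_variants": _run_trapezoid_variants,
    "current_lag": _run_current_lag,
    "rmp_dependence": _run_rmp_dependence,
    "sine_family": _run_sine_family,
    "d2_summation": _run_d2_summation,
    "d2_timing": _run_d2_timing,
    "learning_scaling": _run_learning_scaling,
    "undershoot_mimic": _run_undershoot_mimic,
    "small_withdrawal": _run_small_withdrawal,
    "invivo_phase": _run_invivo_phase,
}


def scenario_names(catalog_path: Optional[str | Path] = None) -> List[str]:
    return sorted(load_scenario_catalog(catalog_path)["scenarios"])


def run_scenario(name: str, config_path: Optional[str | Path] = None,
                 out_dir: Optional[str | Path] = None,
                 seed: Optional[int] = None,
                 dt: Optional[float] = None) -> ScenarioResult:
    """Execute one named scenario and (optionally) write its outputs."""
    catalog = load_scenario_catalog()["scenarios"]
    if name not in catalog:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(catalog)}")
    params = dict(catalog[name])
    kind = params.pop("kind")
    raw = load_raw_config(config_path)
    model = model_from_dict(raw)
    if dt is not None:
        model = replace(model, dt=dt)
    model = _calibrated(model)
    d2 = d2_from_dict(raw.get("d2", {}))
    rec = RecordingSpec.from_dict(raw.get("invivo", {}))
    metrics, traces = _KINDS[kind](model, params, d2, rec, seed)
    result = ScenarioResult(name=name, params={"kind": kind, **params},
                            metrics={k: float(v) for k, v in metrics.items()},
                            traces=traces, seed=seed)
    if out_dir is not None:
        result.write(out_dir)
    return result


_OPS = {
    ">": lambda v, b, tol: v > b,
    ">=": lambda v, b, tol: v >= b,
    "<": lambda v, b, tol: v < b,
    "<=": lambda v, b, tol: v <= b,
    "==": lambda v, b, tol: v == b,
    "~=": lambda v, b, tol: abs(v - b) <= tol,
}


def report(results: Sequence[ScenarioResult],
           thresholds: Optional[Dict[str, Any]] = None) -> pd.DataFrame:
    """Collate scenario metrics against pass/fail thresholds."""
    if not results:
        raise ValueError("need at least one scenario result")
    if thresholds is None:
        thresholds = load_thresholds()["thresholds"]
    rows = []
    for res in results:
        if not res.metrics:
            raise ValueError(f"scenario {res.name!r} produced no metrics")
        checks = thresholds.get(res.name, {})
        for metric, value in sorted(res.metrics.items()):
            row = {"scenario": res.name, "metric": metric, "value": value,
                   "op": "", "bound": np.nan, "status": ""}
            if metric in checks:
                spec = checks[metric]
                ok = _OPS[spec["op"]](value, spec["value"], spec.get("tol", 0.0))
                row.update(op=spec["op"], bound=spec["value"],
                           status="pass" if ok else "fail")
            rows.append(row)
    return pd.DataFrame(rows)
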