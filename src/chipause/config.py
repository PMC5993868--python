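"""Structured-text (YAML) configuration for the model, stimuli and generators.

The published description fixes geometry, leak conductance, maximal
conductances and reversal potentials but cites the gating kinetics to prior
voltage-clamp work without printing them; those kinetics are therefore
configuration, with shipped defaults (``data/model_default.yaml``) chosen to
satisfy the qualitative constraints of the modelled experiments (slow
non-inactivating rectifier with activation midpoint around -30 mV and a
100-300 ms time constant; fast inactivating A-current).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .channels import BellTau, ChannelSpec, GateParams
from .simulator import CellGeometry, ModelConfig
from .stimuli import D2Spec

__all__ = [
    "default_config_path",
    "load_raw_config",
    "model_from_dict",
    "d2_from_dict",
    "load_model_config",
    "load_d2_spec",
    "load_recording_dict",
    "load_scenario_catalog",
    "load_thresholds",
]


def default_config_path() -> Path:
    return Path(resources.files("chipause") / "data" / "model_default.yaml")


def _data_path(name: str) -> Path:
    return Path(resources.files("chipause") / "data" / name)


def load_raw_config(path: Optional[str | Path] = None) -> Dict[str, Any]:
    with open(path or default_config_path()) as fh:
        return yaml.safe_load(fh)


def _gate_from_dict(d: Dict[str, Any]) -> GateParams:
    if "tau_bell" in d and d["tau_bell"] is not None:
        b = d["tau_bell"]
        tau = BellTau(tau_min=float(b["tau_min_ms"]), tau_max=float(b["tau_max_ms"]),
                      v_peak=float(b["v_peak_mV"]), width=float(b["width_mV"]))
    else:
        tau = float(d["tau_ms"])
    return GateParams(v_half=float(d["v_half_mV"]), slope=float(d["slope_mV"]),
                      tau=tau, power=int(d.get("power", 1)))


def channel_from_dict(d: Dict[str, Any]) -> ChannelSpec:
    inact = d.get("inactivation")
    return ChannelSpec(
        name=str(d["name"]),
        gbar=float(d["gbar_mS_cm2"]),
        e_rev=float(d["e_rev_mV"]),
        activation=_gate_from_dict(d["activation"]),
        inactivation=_gate_from_dict(inact) if inact else None,
    )


def model_from_dict(raw: Dict[str, Any]) -> ModelConfig:
    try:
        geom = raw.get("geometry", {})
        geometry = CellGeometry(
            diameter=float(geom.get("diameter_um", 15.0)),
            length=float(geom.get("length_um", 40.0)),
            cm=float(geom.get("cm_uF_cm2", 1.0)),
        )
        leak = raw["leak"]
        channels = [channel_from_dict(c) for c in raw.get("channels", [])]
        return ModelConfig(
            geometry=geometry,
            leak_g=float(leak["g_mS_cm2"]),
            leak_e=float(leak.get("e_mV", -40.0)),
            channels=channels,
            target_rmp=float(raw.get("target_rmp_mV", -40.0)),
            restore_rmp=float(raw.get("restore_rmp_mV", -40.0)),
            holding_current=float(raw.get("holding_current_pA", 0.0)),
            temperature=float(raw.get("temperature_C", 33.0)),
            dt=float(raw.get("dt_ms", 0.025)),
            record_currents=bool(raw.get("record_currents", True)),
        )
    except KeyError as exc:
        raise KeyError(f"invalid model configuration: missing key {exc}") from exc


def d2_from_dict(raw: Dict[str, Any]) -> D2Spec:
    return D2Spec(
        peak=float(raw.get("peak_pA", -10.0)),
        onset_latency=float(raw.get("onset_latency_ms", 100.0)),
        rise_dur=float(raw.get("rise_dur_ms", 150.0)),
        decay_dur=float(raw.get("decay_dur_ms", 300.0)),
        decay_shape=str(raw.get("decay_shape", "linear")),
    )


def load_model_config(path: Optional[str | Path] = None) -> ModelConfig:
    return model_from_dict(load_raw_config(path))


def load_d2_spec(path: Optional[str | Path] = None) -> D2Spec:
    return d2_from_dict(load_raw_config(path).get("d2", {}))


def load_recording_dict(path: Optional[str | Path] = None) -> Dict[str, Any]:
    return dict(load_raw_config(path).get("invivo", {}))


def load_scenario_catalog(path: Optional[str | Path] = None) -> Dict[str, Any]:
    with open(path or _data_path("scenarios.yaml")) as fh:
        return yaml.safe_load(fh)


def load_thresholds(path: Optional[str | Path] = None) -> Dict[str, Any]:
    with open(path or _data_path("thresholds.yaml")) as fh:
        return yaml.safe_load(fh)
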