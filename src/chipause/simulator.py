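"""Single-compartment membrane-equation integrator.

The membrane equation is

    cm * dV/dt = -(I_leak + sum_channels I_ch) + (I_inj + I_hold) / A

with all densities in uA/cm^2, cm in uF/cm^2 and somatic currents in pA
converted through the cylindrical membrane area A.  Gates follow
first-order kinetics and are advanced with exponential Euler; the voltage
update is also exponential (the equation is linear in V for frozen gates),
which keeps the fixed-step scheme stable and convergent at dt = 0.025 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .channels import BellTau, ChannelSpec, steady_state, time_constant
from .stimuli import StimulusWaveform

__all__ = [
    "CellGeometry",
    "ModelConfig",
    "VoltageTrace",
    "VClampStepResult",
    "membrane_area",
    "calibrate_resting_potential",
    "resting_potential",
    "holding_for_voltage",
    "simulate_current_clamp",
    "simulate_voltage_steps",
    "apply_pharmacology",
    "PHARMACOLOGY_SCENARIOS",
]

PA_TO_UA = 1e-6
DIVERGENCE_LIMIT_MV = 500.0


@dataclass(frozen=True)
class CellGeometry:
    """Cylindrical compartment geometry (lateral surface only)."""

    diameter: float = 15.0  # um
    length: float = 40.0  # um
    cm: float = 1.0  # uF/cm^2

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0 or self.cm <= 0:
            raise ValueError("geometry values must be > 0")


def membrane_area(geometry: CellGeometry) -> float:
    """Lateral cylinder surface pi*d*L in cm^2 (inputs in um)."""
    return math.pi * geometry.diameter * geometry.length * 1e-8


@dataclass
class ModelConfig:
    """Complete description of the single-compartment model."""

    geometry: CellGeometry = field(default_factory=CellGeometry)
    leak_g: float = 0.09  # mS/cm^2
    leak_e: float = -40.0  # mV (usually set by calibrate_resting_potential)
    channels: List[ChannelSpec] = field(default_factory=list)
    enabled: Dict[str, bool] = field(default_factory=dict)
    target_rmp: float = -40.0  # mV
    restore_rmp: float = -40.0  # mV, re-depolarization level for zd7288_restored
    holding_current: float = 0.0  # pA
    temperature: float = 33.0  # degC, metadata only
    dt: float = 0.025  # ms
    record_currents: bool = True

    def __post_init__(self) -> None:
        if self.leak_g <= 0:
            raise ValueError("leak_g must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        names = [c.name for c in self.channels]
        if len(names) != len(set(names)):
            raise ValueError("channel names must be unique")

    def active_channels(self) -> List[ChannelSpec]:
        return [c for c in self.channels
                if self.enabled.get(c.name, True) and c.gbar > 0]

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_channel_gbar(self, name: str, gbar: float) -> "ModelConfig":
        new = [replace(c, gbar=gbar) if c.name == name else c for c in self.channels]
        return replace(self, channels=new)

    def with_only(self, names: Sequence[str]) -> "ModelConfig":
        """Copy with only the named channels enabled (leak always present)."""
        enabled = {c.name: c.name in names for c in self.channels}
        unknown = set(names) - {c.name for c in self.channels}
        if unknown:
            raise KeyError(f"unknown channels: {sorted(unknown)}")
        return replace(self, enabled=enabled)


@dataclass
class VoltageTrace:
    """Simulated membrane potential with optional per-channel densities."""

    time: np.ndarray  # ms
    v: np.ndarray  # mV
    i_inj: np.ndarray  # pA (as injected at the soma, excludes holding)
    currents: Dict[str, np.ndarray] = field(default_factory=dict)  # uA/cm^2

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_array(self) -> Tuple[np.ndarray, List[str]]:
        cols = [self.time, self.v, self.i_inj]
        names = ["time_ms", "v_mV", "i_inj_pA"]
        for name in sorted(self.currents):
            cols.append(self.currents[name])
            names.append(f"i_{name}_uA_cm2")
        return np.column_stack(cols), names

    def write_text(self, path: str | Path) -> None:
        data, names = self.to_array()
        np.savetxt(path, data, delimiter="\t", header="\t".join(names), comments="")

    @classmethod
    def read_text(cls, path: str | Path) -> "VoltageTrace":
        with open(path) as fh:
            names = fh.readline().split()
        data = np.loadtxt(path, skiprows=1)
        currents = {}
        for j, name in enumerate(names):
            if name.startswith("i_") and name.endswith("_uA_cm2"):
                currents[name[2:-len("_uA_cm2")]] = data[:, j]
        return cls(data[:, 0], data[:, 1], data[:, 2], currents)


@dataclass
class VClampStepResult:
    """Per-channel current-density families from a voltage-step protocol."""

    holding: float
    levels: np.ndarray  # mV, strictly increasing
    time: np.ndarray  # ms from step onset
    currents: Dict[str, np.ndarray]  # name -> (n_levels, n_time) uA/cm^2


# ---------------------------------------------------------------------------
# steady-state machinery


def _steady_density(v: float, config: ModelConfig) -> float:
    """Total steady-state membrane current density (uA/cm^2) at voltage v,
    minus the holding-current density."""
    total = config.leak_g * (v - config.leak_e)
    for spec in config.active_channels():
        m = steady_state(v, spec.activation) ** spec.activation.power
        if spec.inactivation is not None:
            m *= steady_state(v, spec.inactivation) ** spec.inactivation.power
        total += spec.gbar * m * (v - spec.e_rev)
    hold_dens = config.holding_current * PA_TO_UA / membrane_area(config.geometry)
    return total - hold_dens


def resting_potential(config: ModelConfig, bracket: Tuple[float, float] = (-150.0, 50.0),
                      ) -> float:
    """Zero-input steady-state voltage (includes any holding current)."""
    lo, hi = bracket
    grid = np.linspace(lo, hi, 201)
    vals = np.array([_steady_density(v, config) for v in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) <= 0)
    if sign_change.size == 0:
        raise RuntimeError("no resting potential found in bracket")
    j = sign_change[0]
    return float(brentq(lambda v: _steady_density(v, config), grid[j], grid[j + 1],
                        xtol=1e-10))


def calibrate_resting_potential(config: ModelConfig, *, verify: bool = True,
                                settle_ms: float = 2000.0,
                                bounds: Tuple[float, float] = (-120.0, 0.0),
                                ) -> float:
    """Leak reversal potential that puts the zero-input steady state at
    ``config.target_rmp``.

    The balance equation is solved exactly for ``leak_e``; the result must
    lie in ``bounds`` (else a RuntimeError).  With ``verify`` a 2 s settling
    simulation checks the settled voltage is within 0.1 mV of target.
    """
    v = config.target_rmp
    k_current = 0.0
    for spec in config.active_channels():
        m = steady_state(v, spec.activation) ** spec.activation.power
        if spec.inactivation is not None:
            m *= steady_state(v, spec.inactivation) ** spec.inactivation.power
        k_current += spec.gbar * m * (v - spec.e_rev)
    hold_dens = config.holding_current * PA_TO_UA / membrane_area(config.geometry)
    leak_e = v + (k_current - hold_dens) / config.leak_g
    if not bounds[0] <= leak_e <= bounds[1]:
        raise RuntimeError(
            f"calibrated leak reversal {leak_e:.2f} mV outside {bounds}; "
            "channel conductances too large at the target potential")
    if verify:
        cfg = replace(config, leak_e=leak_e)
        zero = StimulusWaveform(np.array([0.0, settle_ms]), np.zeros(2))
        trace = simulate_current_clamp(cfg, zero, record_currents=False)
        if abs(trace.v[-1] - config.target_rmp) > 0.1:
            raise RuntimeError(
                f"settled potential {trace.v[-1]:.3f} mV missed target "
                f"{config.target_rmp} mV")
    return float(leak_e)


def calibrated(config: ModelConfig, **kwargs) -> ModelConfig:
    """Copy of ``config`` with ``leak_e`` calibrated to ``target_rmp``."""
    return replace(config, leak_e=calibrate_resting_potential(config, **kwargs))


def holding_for_voltage(config: ModelConfig, v: float) -> float:
    """Somatic holding current (pA) that moves the steady state to ``v``."""
    cfg = replace(config, holding_current=0.0)
    density = _steady_density(v, cfg)
    return density * membrane_area(config.geometry) / PA_TO_UA


# ---------------------------------------------------------------------------
# current clamp


class _GateRuntime:
    """Precomputed update constants for one gate (speed: pure-python loop)."""

    __slots__ = ("v_half", "inv_slope", "power", "const_decay", "bell", "dt")

    def __init__(self, p, dt: float):
        self.v_half = p.v_half
        self.inv_slope = 1.0 / p.slope
        self.power = p.power
        self.dt = dt
        if isinstance(p.tau, BellTau):
            self.bell = p.tau
            self.const_decay = None
        else:
            self.bell = None
            self.const_decay = -math.expm1(-dt / float(p.tau))

    def inf(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp(-(v - self.v_half) * self.inv_slope))

    def decay(self, v: float) -> float:
        if self.const_decay is not None:
            return self.const_decay
        return -math.expm1(-self.dt / self.bell(v))


def simulate_current_clamp(config: ModelConfig, stim: StimulusWaveform, *,
                           v_init: Optional[float] = None,
                           record_currents: Optional[bool] = None,
                           ) -> VoltageTrace:
    """Integrate the membrane equation under an injected-current waveform.

    Gates start at their steady state for the initial voltage (the resting
    potential by default), so a zero stimulus gives a flat trace.
    """
    if record_currents is None:
        record_currents = config.record_currents
    if not np.all(np.isfinite(stim.current)):
        raise ValueError("stimulus contains non-finite values")
    stim = stim.resample(config.dt)
    dt = config.dt
    cm = config.geometry.cm
    area = membrane_area(config.geometry)
    hold_dens = config.holding_current * PA_TO_UA / area
    inj_dens = stim.current * (PA_TO_UA / area)

    v = resting_potential(config) if v_init is None else float(v_init)
    specs = config.active_channels()
    gates_m: List[float] = []
    gates_h: List[Optional[float]] = []
    rt: List[Tuple[float, float, _GateRuntime, Optional[_GateRuntime]]] = []
    for spec in specs:
        act = _GateRuntime(spec.activation, dt)
        inact = _GateRuntime(spec.inactivation, dt) if spec.inactivation else None
        rt.append((spec.gbar, spec.e_rev, act, inact))
        gates_m.append(act.inf(v))
        gates_h.append(inact.inf(v) if inact else None)

    n = stim.time.size
    v_out = np.empty(n)
    cur_out = {spec.name: np.empty(n) for spec in specs} if record_currents else {}
    cur_views = [cur_out[spec.name] if record_currents else None for spec in specs]

    leak_g = config.leak_g
    leak_drive = leak_g * config.leak_e + hold_dens
    exp = math.exp
    for k in range(n):
        g_sum = leak_g
        drive = leak_drive + inj_dens[k]
        for j, (gbar, e_rev, act, inact) in enumerate(rt):
            m = gates_m[j]
            open_f = m if act.power == 1 else m ** act.power
            h = gates_h[j]
            if inact is not None:
                open_f *= h if inact.power == 1 else h ** inact.power
            g = gbar * open_f
            g_sum += g
            drive += g * e_rev
            if cur_views[j] is not None:
                cur_views[j][k] = g * (v - e_rev)
            # gate update (exponential Euler at the pre-step voltage)
            gates_m[j] = m + (act.inf(v) - m) * act.decay(v)
            if inact is not None:
                gates_h[j] = h + (inact.inf(v) - h) * inact.decay(v)
        v_out[k] = v
        v_inf = drive / g_sum
        v = v_inf + (v - v_inf) * exp(-dt * g_sum / cm)
        if not -DIVERGENCE_LIMIT_MV < v < DIVERGENCE_LIMIT_MV:
            raise RuntimeError(
                f"solver divergence: |V| exceeded {DIVERGENCE_LIMIT_MV} mV "
                f"at t = {stim.time[k]:.3f} ms")
    return VoltageTrace(stim.time.copy(), v_out, stim.current.copy(), cur_out)


# ---------------------------------------------------------------------------
# voltage clamp


def simulate_voltage_steps(config: ModelConfig, holding: float, step: float,
                           n_steps: int, step_dur: float,
                           ) -> VClampStepResult:
    """Voltage-step families: gates start at steady state for ``holding``,
    then relax exponentially at each clamped level (closed-form kinetics)."""
    if step <= 0 or n_steps < 1 or step_dur <= 0:
        raise ValueError("step, n_steps and step_dur must be positive")
    levels = holding + step * np.arange(1, n_steps + 1)
    t = np.arange(int(round(step_dur / config.dt)) + 1) * config.dt
    currents: Dict[str, np.ndarray] = {}
    for spec in config.active_channels():
        fam = np.empty((levels.size, t.size))
        for i, v in enumerate(levels):
            open_f = np.ones_like(t)
            for gate in (spec.activation, spec.inactivation):
                if gate is None:
                    continue
                x0 = steady_state(holding, gate)
                x_inf = steady_state(v, gate)
                tau = time_constant(v, gate)
                x = x_inf + (x0 - x_inf) * np.exp(-t / tau)
                open_f = open_f * x ** gate.power
            fam[i] = spec.gbar * open_f * (v - spec.e_rev)
        currents[spec.name] = fam
    return VClampStepResult(holding, levels, t, currents)


# ---------------------------------------------------------------------------
# in-silico pharmacology

PHARMACOLOGY_SCENARIOS = (
    "control", "xe991_or_tea", "four_ap", "zd7288", "zd7288_restored",
)


def apply_pharmacology(config: ModelConfig, scenario: str) -> ModelConfig:
    """Channel-ablation / RMP-shift counterparts of the blocker experiments.

    * ``control``: unchanged copy.
    * ``xe991_or_tea``: Kv7 block, slow rectifier conductance to zero
      (RMP held at the pre-drug level by recalibration).
    * ``four_ap``: fast A-current conductance to zero.
    * ``zd7288``: HCN block, target RMP moved to -76 mV.
    * ``zd7288_restored``: HCN block plus a depolarizing holding current
      restoring the membrane to ``config.restore_rmp``.
    """
    if scenario not in PHARMACOLOGY_SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid: {list(PHARMACOLOGY_SCENARIOS)}")
    if scenario == "control":
        return replace(config)
    if scenario == "xe991_or_tea":
        new = config.with_channel_gbar("kr", 0.0)
        return calibrated(new, verify=False)
    if scenario == "four_ap":
        new = config.with_channel_gbar("a", 0.0)
        return calibrated(new, verify=False)
    new = replace(config, target_rmp=-76.0, holding_current=0.0)
    new = calibrated(new, verify=False)
    if scenario == "zd7288_restored":
        hold = holding_for_voltage(new, config.restore_rmp)
        new = replace(new, holding_current=hold)
    return new
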