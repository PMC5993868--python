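"""Hodgkin-Huxley style gating and current densities for the model's K+ channels.

Conventions (used everywhere in this package):

* outward membrane current is positive,
* depolarizing injected current is positive,
* voltages in mV, time in ms, conductance densities in mS/cm^2,
  current densities in uA/cm^2.

Steady-state activation/inactivation follows the Boltzmann form
``1 / (1 + exp(-(v - v_half) / slope))`` with first-order relaxation
``dx/dt = (x_inf(v) - x) / tau(v)``.  The voltage-dependent time constant
is either a constant or a Gaussian-in-voltage "bell" between ``tau_min``
(far from ``v_peak``) and ``tau_max`` (at ``v_peak``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

__all__ = [
    "BellTau",
    "GateParams",
    "ChannelSpec",
    "GateState",
    "steady_state",
    "time_constant",
    "gate_derivative",
    "current_density",
    "steady_gate_state",
]


@dataclass(frozen=True)
class BellTau:
    """Bell-shaped voltage dependence of a gating time constant (ms)."""

    tau_min: float
    tau_max: float
    v_peak: float
    width: float

    def __post_init__(self) -> None:
        if not (self.tau_min > 0 and self.tau_max > 0):
            raise ValueError("time constants must be > 0")
        if self.tau_max < self.tau_min:
            raise ValueError("tau_max must be >= tau_min")
        if self.width <= 0:
            raise ValueError("width must be > 0")

    def __call__(self, v: float) -> float:
        z = (v - self.v_peak) / self.width
        return self.tau_min + (self.tau_max - self.tau_min) * math.exp(-0.5 * z * z)


TauSpec = Union[float, BellTau]


@dataclass(frozen=True)
class GateParams:
    """Boltzmann midpoint/slope plus relaxation time constant for one gate.

    ``slope`` is signed: positive for activation-like gates (open with
    depolarization), negative for inactivation-like gates.
    """

    v_half: float
    slope: float
    tau: TauSpec
    power: int = 1

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be non-zero")
        if isinstance(self.tau, (int, float)) and self.tau <= 0:
            raise ValueError("time constant must be > 0")
        if self.power < 1 or int(self.power) != self.power:
            raise ValueError("power must be a positive integer")


@dataclass(frozen=True)
class ChannelSpec:
    """Maximal conductance, reversal potential and gating of one channel."""

    name: str
    gbar: float
    e_rev: float
    activation: GateParams
    inactivation: Optional[GateParams] = None

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")

    @property
    def inactivating(self) -> bool:
        return self.inactivation is not None


@dataclass
class GateState:
    """Fractional open state of the gates of one channel, each in [0, 1]."""

    m: float
    h: Optional[float] = None

    def __post_init__(self) -> None:
        for value in (self.m, self.h):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"gate value {value} outside [0, 1]")


def steady_state(v: float, p: GateParams) -> float:
    """Boltzmann steady-state open fraction of a gate at voltage ``v``."""
    if not math.isfinite(v):
        raise ValueError("voltage must be finite")
    return 1.0 / (1.0 + math.exp(-(v - p.v_half) / p.slope))


def time_constant(v: float, p: GateParams) -> float:
    """Gate relaxation time constant (ms) at voltage ``v``."""
    if not math.isfinite(v):
        raise ValueError("voltage must be finite")
    if isinstance(p.tau, BellTau):
        return p.tau(v)
    return float(p.tau)


def gate_derivative(v: float, x: float, p: GateParams) -> float:
    """First-order relaxation rate dx/dt (1/ms) toward the steady state."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"gate value {x} outside [0, 1]")
    return (steady_state(v, p) - x) / time_constant(v, p)


def steady_gate_state(v: float, spec: ChannelSpec) -> GateState:
    """Gate state with every gate at its steady-state value for ``v``."""
    h = steady_state(v, spec.inactivation) if spec.inactivation else None
    return GateState(m=steady_state(v, spec.activation), h=h)


def current_density(v: float, gates: GateState, spec: ChannelSpec) -> float:
    """Membrane current density (uA/cm^2, outward positive) of one channel.

    ``gbar * m**p_m * [h**p_h] * (v - e_rev)``; note mS/cm^2 * mV = uA/cm^2.
    """
    if spec.inactivating and gates.h is None:
        raise ValueError(f"channel {spec.name!r} requires an inactivation gate")
    if not spec.inactivating and gates.h is not None:
        raise ValueError(f"channel {spec.name!r} has no inactivation gate")
    open_fraction = gates.m ** spec.activation.power
    if spec.inactivation is not None:
        open_fraction *= gates.h ** spec.inactivation.power
    return spec.gbar * open_fraction * (v - spec.e_rev)
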