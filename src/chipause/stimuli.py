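"""Injected-current waveform builders (sine, trapezoid, D2-shaped, composites).

All waveforms are uniformly sampled somatic currents in pA (depolarizing
positive) on a millisecond grid starting at t = 0 unless shifted during
composition.  Named epochs (e.g. ``ramp_up``, ``plateau``) annotate the
waveform so that downstream metrics can locate input onset/offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "StimulusWaveform",
    "D2Spec",
    "sine_current",
    "trapezoid_current",
    "step_current",
    "d2_current",
    "compose_scenario",
    "negative_undershoot_mimic",
    "UNDERSHOOT_TEMPLATE_DUR_MS",
]

DEFAULT_DT = 0.025  # ms

Epoch = Tuple[float, float]


@dataclass
class StimulusWaveform:
    """Uniformly sampled injected current (pA) with named epochs."""

    time: np.ndarray  # ms, uniform grid
    current: np.ndarray  # pA
    annotations: Dict[str, Epoch] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape or self.time.ndim != 1:
            raise ValueError("time and current must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("waveform needs at least two samples")
        steps = np.diff(self.time)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("current contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def input_window(self, threshold: float = 1e-12) -> Epoch:
        """(onset, offset) of the support of non-zero current."""
        nz = np.flatnonzero(np.abs(self.current) > threshold)
        if nz.size == 0:
            return (float(self.time[0]), float(self.time[0]))
        return (float(self.time[nz[0]]), float(self.time[nz[-1]]))

    def resample(self, dt: float) -> "StimulusWaveform":
        """Linear-interpolation resample onto a new uniform grid."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if abs(dt - self.dt) < 1e-12:
            return StimulusWaveform(self.time.copy(), self.current.copy(), dict(self.annotations))
        n = int(round(self.duration / dt))
        t = self.time[0] + np.arange(n + 1) * dt
        i = np.interp(t, self.time, self.current)
        return StimulusWaveform(t, i, dict(self.annotations))

    def write_text(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.time, self.current]),
                   header="time_ms\tcurrent_pA", delimiter="\t", comments="")

    @classmethod
    def read_text(cls, path: str | Path) -> "StimulusWaveform":
        data = np.loadtxt(path, skiprows=1)
        return cls(data[:, 0], data[:, 1])


def _grid(total_ms: float, dt: float) -> np.ndarray:
    if total_ms <= 0:
        raise ValueError("total duration must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = int(round(total_ms / dt))
    return np.arange(n + 1) * dt


@dataclass(frozen=True)
class D2Spec:
    """Shape of the dopamine D2-receptor-mediated hyperpolarizing current.

    The rise is a quarter sine (matching the rise of phasic dopamine-neuron
    activity); the decay back to zero is linear by default or exponential.
    Peak is hyperpolarizing by convention (``peak <= 0``).
    """

    peak: float = -10.0  # pA, <= 0
    onset_latency: float = 100.0  # ms
    rise_dur: float = 150.0  # ms
    decay_dur: float = 300.0  # ms
    decay_shape: str = "linear"  # or "exponential"

    def __post_init__(self) -> None:
        if self.peak > 0:
            raise ValueError("D2 current is hyperpolarizing: peak must be <= 0")
        if self.rise_dur <= 0 or self.decay_dur <= 0:
            raise ValueError("durations must be > 0")
        if self.onset_latency < 0:
            raise ValueError("onset_latency must be >= 0")
        if self.decay_shape not in ("linear", "exponential"):
            raise ValueError("decay_shape must be 'linear' or 'exponential'")

    @property
    def total_dur(self) -> float:
        return self.onset_latency + self.rise_dur + self.decay_dur


def sine_current(amplitude: float, freq: float, duration: float,
                 offset: float = 0.0, *, dt: float = DEFAULT_DT,
                 tail: float = 0.0) -> StimulusWaveform:
    """Depolarizing-first sine cycle: ``offset + A sin(2 pi f t)`` on
    ``[0, duration]`` and zero afterwards (``tail`` ms of silence appended).

    With ``freq`` = 2 Hz and ``duration`` = 500 ms this is exactly one full
    cycle; ``duration`` = 250 ms gives the depolarizing half-wave only.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    t = _grid(duration + tail, dt)
    i = np.zeros_like(t)
    active = t <= duration + 1e-9
    i[active] = offset + amplitude * np.sin(2.0 * math.pi * freq * 1e-3 * t[active])
    # the sample at t == duration belongs to the silent tail for a full cycle
    ann = {"sine": (0.0, float(duration))}
    return StimulusWaveform(t, i, ann)


def trapezoid_current(peak: float, ramp_up: float, plateau: float,
                      ramp_down: float, sign: int = 1, *,
                      dt: float = DEFAULT_DT, onset: float = 0.0,
                      tail: float = 0.0) -> StimulusWaveform:
    """Piecewise-linear ramp/plateau/ramp current of amplitude ``sign*peak``."""
    if min(ramp_up, plateau, ramp_down) < 0:
        raise ValueError("phase durations must be >= 0")
    if ramp_up + plateau + ramp_down == 0:
        raise ValueError("at least one phase must have non-zero duration")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    total = onset + ramp_up + plateau + ramp_down + tail
    t = _grid(total, dt)
    t0, t1 = onset, onset + ramp_up
    t2, t3 = t1 + plateau, t1 + plateau + ramp_down
    i = np.zeros_like(t)
    if ramp_up > 0:
        sel = (t >= t0) & (t < t1)
        i[sel] = (t[sel] - t0) / ramp_up
    sel = (t >= t1) & (t <= t2)
    i[sel] = 1.0
    if ramp_down > 0:
        sel = (t > t2) & (t <= t3)
        i[sel] = (t3 - t[sel]) / ramp_down
    i *= sign * peak
    ann = {"ramp_up": (t0, t1), "plateau": (t1, t2), "ramp_down": (t2, t3)}
    return StimulusWaveform(t, i, ann)


def step_current(amplitude: float, duration: float, *, dt: float = DEFAULT_DT,
                 onset: float = 0.0, tail: float = 0.0) -> StimulusWaveform:
    """Rectangular current step (degenerate trapezoid with zero ramps)."""
    sign = 1 if amplitude >= 0 else -1
    return trapezoid_current(abs(amplitude), 0.0, duration, 0.0, sign,
                             dt=dt, onset=onset, tail=tail)


def d2_current(spec: D2Spec, *, dt: float = DEFAULT_DT,
               tail: float = 0.0) -> StimulusWaveform:
    """D2-receptor current: latency, quarter-sine rise to peak, decay to zero."""
    t = _grid(spec.total_dur + tail, dt)
    i = np.zeros_like(t)
    t_rise0 = spec.onset_latency
    t_peak = t_rise0 + spec.rise_dur
    t_end = t_peak + spec.decay_dur
    sel = (t >= t_rise0) & (t <= t_peak)
    i[sel] = np.sin(0.5 * math.pi * (t[sel] - t_rise0) / spec.rise_dur)
    sel = (t > t_peak) & (t <= t_end)
    if spec.decay_shape == "linear":
        i[sel] = 1.0 - (t[sel] - t_peak) / spec.decay_dur
    else:
        tau = spec.decay_dur / 4.0
        i[sel] = np.exp(-(t[sel] - t_peak) / tau)
        i[t > t_end] = 0.0
    i *= spec.peak
    ann = {"d2_onset": (t_rise0, t_peak), "d2": (t_rise0, t_end)}
    return StimulusWaveform(t, i, ann)


def compose_scenario(parts: Sequence[Tuple[StimulusWaveform, float, float]],
                     ) -> StimulusWaveform:
    """Pointwise sum of time-shifted, scaled waveforms sharing one dt.

    ``parts`` is a sequence of ``(waveform, t_shift_ms, scale)``.  Shifts are
    rounded to the common sample grid.  The composite spans the union of the
    shifted supports; epochs are merged (shifted), later parts suffixed on
    name collision.
    """
    if not parts:
        raise ValueError("need at least one part")
    dt = parts[0][0].dt
    for wf, _, _ in parts:
        if abs(wf.dt - dt) > 1e-9:
            raise ValueError("all parts must share the same dt")
    starts = [shift + wf.time[0] for wf, shift, _ in parts]
    ends = [shift + wf.time[-1] for wf, shift, _ in parts]
    t0 = min(starts)
    n = int(round((max(ends) - t0) / dt))
    t = t0 + np.arange(n + 1) * dt
    i = np.zeros_like(t)
    ann: Dict[str, Epoch] = {}
    for k, (wf, shift, scale) in enumerate(parts):
        j0 = int(round((shift + wf.time[0] - t0) / dt))
        i[j0:j0 + wf.time.size] += scale * wf.current
        for name, (a, b) in wf.annotations.items():
            key = name if name not in ann else f"{name}_{k}"
            ann[key] = (a + shift, b + shift)
    return StimulusWaveform(t, i, ann)


#: duration (ms) of the canonical undershoot-shaped template
UNDERSHOOT_TEMPLATE_DUR_MS = 500.0


def negative_undershoot_mimic(r_in: float, v_target: float, *,
                              dt: float = DEFAULT_DT, tail: float = 0.0,
                              trough_dur: float = UNDERSHOOT_TEMPLATE_DUR_MS,
                              ) -> StimulusWaveform:
    """Negative current reproducing a given hyperpolarization by Ohm's law.

    Amplitude is ``-(v_target / r_in)`` (mV over megaohm gives nA, reported
    in pA): 2.72 mV across 200 MOhm gives -13.6 pA.  The shape is a slow
    raised-cosine trough with recovery, mimicking the K+-current-driven
    undershoot that follows excitatory input withdrawal.
    """
    if r_in <= 0:
        raise ValueError("input resistance must be > 0")
    amplitude_pa = -(v_target / r_in) * 1e3  # mV / MOhm = nA -> pA
    t = _grid(trough_dur + tail, dt)
    i = np.zeros_like(t)
    sel = t <= trough_dur
    i[sel] = amplitude_pa * 0.5 * (1.0 - np.cos(2.0 * math.pi * t[sel] / trough_dur))
    ann = {"trough": (0.0, float(trough_dur))}
    return StimulusWaveform(t, i, ann)
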