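"""Synthetic in-vivo-like recordings with known ground truth.

Generates an inverted-LFP-like slow oscillation (~1 Hz sinusoid plus noise)
and phase-coupled spike trains: a tonically active unit whose rate follows
the *derivative* of the oscillation (a differentiator-like response, so the
rate peaks on the rising phase and dips below baseline on the receding
phase) and a projection-neuron-like unit whose modulation lags it by a
configurable phase.  Spikes are drawn from an inhomogeneous Poisson process
by thinning, with an absolute refractory period.  Everything is reproducible
from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .metrics import SpikeTrain

__all__ = [
    "RecordingSpec",
    "Trace",
    "RateProfile",
    "SyntheticRecording",
    "generate_ilfp",
    "chi_rate_profile",
    "spn_rate_profile",
    "sample_spikes",
    "pause_scenario",
    "generate_recording",
]


@dataclass(frozen=True)
class RecordingSpec:
    """Parameters of one synthetic recording session."""

    slow_freq: float = 1.0  # Hz
    lfp_amplitude: float = 1.0  # a.u.
    noise_sd: float = 0.1  # a.u.
    n_sweeps: int = 100
    duration_ms: float = 10000.0
    dt_ms: float = 1.0
    chi_baseline: float = 6.0  # Hz, tonic 3-10 Hz range
    chi_mod_depth: float = 0.8  # fraction of baseline
    spn_baseline: float = 2.0  # Hz
    spn_lag: float = 60.0  # degrees of the slow cycle
    refractory: float = 20.0  # ms
    smooth_ms: float = 50.0  # derivative pre-smoothing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chi_baseline < 0 or self.spn_baseline < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.chi_mod_depth <= 1.0:
            raise ValueError("mod depth must be in [0, 1]")
        if self.slow_freq <= 0 or self.duration_ms <= 0 or self.dt_ms <= 0:
            raise ValueError("slow_freq, duration and dt must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @classmethod
    def from_dict(cls, raw: Dict) -> "RecordingSpec":
        """Build a spec from the structured-config keys (unit-suffixed)."""
        key_map = {
            "slow_freq_hz": "slow_freq",
            "lfp_amplitude": "lfp_amplitude",
            "noise_sd": "noise_sd",
            "n_sweeps": "n_sweeps",
            "duration_ms": "duration_ms",
            "dt_ms": "dt_ms",
            "chi_baseline_hz": "chi_baseline",
            "chi_mod_depth": "chi_mod_depth",
            "spn_baseline_hz": "spn_baseline",
            "spn_lag_deg": "spn_lag",
            "refractory_ms": "refractory",
            "smooth_ms": "smooth_ms",
            "seed": "seed",
        }
        kwargs = {key_map[k]: v for k, v in raw.items() if k in key_map}
        return cls(**kwargs)


@dataclass
class Trace:
    """Uniformly sampled scalar signal (time in ms)."""

    time: np.ndarray
    value: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class RateProfile:
    """Ground-truth instantaneous firing rate (Hz) on a uniform grid."""

    time: np.ndarray  # ms
    rate: np.ndarray  # Hz
    modulation: np.ndarray = field(default=None)  # normalized, in [-1, 1]

    def __post_init__(self) -> None:
        if np.any(self.rate < 0):
            raise ValueError("rates must be >= 0")
        if self.modulation is None:
            self.modulation = np.zeros_like(self.rate)


@dataclass
class SyntheticRecording:
    """Generated iLFP, labeled spike trains and their ground-truth profiles."""

    ilfp: Trace
    trains: Dict[str, List[SpikeTrain]]
    profiles: Dict[str, RateProfile]
    spec: RecordingSpec


def _grid(spec: RecordingSpec) -> np.ndarray:
    # endpoint-exclusive so whole-cycle recordings are exactly periodic
    # (circular smoothing and phase shifts then wrap cleanly)
    n = int(round(spec.duration_ms / spec.dt_ms))
    return np.arange(n) * spec.dt_ms


def generate_ilfp(spec: RecordingSpec,
                  rng: Optional[np.random.Generator] = None) -> Trace:
    """Sinusoid at ``slow_freq`` plus seeded Gaussian noise."""
    rng = rng or spec.rng()
    t = _grid(spec)
    value = spec.lfp_amplitude * np.sin(2.0 * math.pi * spec.slow_freq * 1e-3 * t)
    if spec.noise_sd > 0:
        value = value + rng.normal(0.0, spec.noise_sd, size=t.size)
    return Trace(t, value)


def _normalized_derivative(ilfp: Trace, spec: RecordingSpec) -> np.ndarray:
    """Smoothed d(iLFP)/dt scaled to unit maximum magnitude."""
    value = ilfp.value
    if spec.smooth_ms > 0:
        value = gaussian_filter1d(value, spec.smooth_ms / ilfp.dt, mode="wrap")
    grad = np.gradient(value, ilfp.time)
    peak = float(np.max(np.abs(grad)))
    if peak == 0:
        return np.zeros_like(grad)
    return grad / peak


def chi_rate_profile(ilfp: Trace, spec: RecordingSpec) -> RateProfile:
    """Differentiator-like tonic-unit profile: baseline modulated by the
    normalized iLFP derivative, so the rate maximum precedes the iLFP
    maximum and the minimum falls on the receding phase."""
    mod = _normalized_derivative(ilfp, spec)
    rate = np.clip(spec.chi_baseline * (1.0 + spec.chi_mod_depth * mod), 0.0, None)
    return RateProfile(ilfp.time.copy(), rate, mod)


def spn_rate_profile(ilfp: Trace, spec: RecordingSpec) -> RateProfile:
    """Projection-neuron profile: the tonic-unit modulation delayed by
    ``spn_lag`` degrees of the slow cycle (circular shift; the default
    duration is a whole number of cycles)."""
    mod = _normalized_derivative(ilfp, spec)
    lag_ms = spec.spn_lag / 360.0 / spec.slow_freq * 1e3
    shift = int(round(lag_ms / ilfp.dt))
    mod_shifted = np.roll(mod, shift)
    rate = np.clip(spec.spn_baseline * (1.0 + spec.chi_mod_depth * mod_shifted),
                   0.0, None)
    return RateProfile(ilfp.time.copy(), rate, mod_shifted)


def sample_spikes(profile: RateProfile, spec: RecordingSpec,
                  rng: Optional[np.random.Generator] = None,
                  n_sweeps: Optional[int] = None) -> List[SpikeTrain]:
    """Inhomogeneous Poisson spike trains by thinning, one per sweep, with
    an absolute refractory period enforced after thinning."""
    rng = rng or spec.rng()
    n_sweeps = spec.n_sweeps if n_sweeps is None else n_sweeps
    t0, t1 = float(profile.time[0]), float(profile.time[-1])
    r_max = float(profile.rate.max())
    trains: List[SpikeTrain] = []
    for sweep in range(n_sweeps):
        if r_max <= 0:
            trains.append(SpikeTrain(np.empty(0), sweep_id=sweep))
            continue
        n = rng.poisson(r_max * (t1 - t0) * 1e-3)
        cand = np.sort(rng.uniform(t0, t1, size=n))
        u = rng.uniform(0.0, r_max, size=n)
        accepted = cand[u < np.interp(cand, profile.time, profile.rate)]
        if spec.refractory > 0 and accepted.size:
            kept = [accepted[0]]
            for t in accepted[1:]:
                if t - kept[-1] > spec.refractory:
                    kept.append(t)
            accepted = np.asarray(kept)
        trains.append(SpikeTrain(accepted, sweep_id=sweep))
    return trains


def pause_scenario(depth_pct: float, duration_ms: float,
                   rebound_pct: float = 100.0, spec: RecordingSpec = RecordingSpec(),
                   *, onset_ms: float = 1000.0, rebound_duration_ms: float = 200.0,
                   ) -> Tuple[RateProfile, Dict[str, float]]:
    """Baseline rate profile with an inserted pause (and optional rebound).

    Returns the profile and the ground truth used to build it; the pause is
    a rectangular rate dip of ``depth_pct`` percent of baseline lasting
    ``duration_ms``, optionally followed by a rebound bump at
    ``rebound_pct`` percent of baseline.
    """
    if not 0.0 <= depth_pct <= 100.0:
        raise ValueError("depth must be in [0, 100] percent")
    t = _grid(spec)
    rate = np.full(t.size, spec.chi_baseline)
    in_pause = (t >= onset_ms) & (t < onset_ms + duration_ms)
    rate[in_pause] = spec.chi_baseline * (1.0 - depth_pct / 100.0)
    if rebound_pct > 100.0:
        r0 = onset_ms + duration_ms
        in_reb = (t >= r0) & (t < r0 + rebound_duration_ms)
        rate[in_reb] = spec.chi_baseline * rebound_pct / 100.0
    truth = {
        "baseline_hz": spec.chi_baseline,
        "pause_amplitude_pct": 100.0 - depth_pct,
        "pause_onset_ms": onset_ms,
        "pause_duration_ms": duration_ms,
        "rebound_amplitude_pct": rebound_pct,
    }
    return RateProfile(t, rate), truth


def generate_recording(spec: RecordingSpec) -> SyntheticRecording:
    """Full synthetic session: iLFP plus ChI-like and SPN-like spike trains
    sampled from their ground-truth profiles (single seeded RNG stream)."""
    rng = spec.rng()
    ilfp = generate_ilfp(spec, rng)
    chi = chi_rate_profile(ilfp, spec)
    spn = spn_rate_profile(ilfp, spec)
    trains = {
        "chi": sample_spikes(chi, spec, rng),
        "spn": sample_spikes(spn, spec, rng),
    }
    return SyntheticRecording(ilfp, trains, {"chi": chi, "spn": spn}, spec)
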