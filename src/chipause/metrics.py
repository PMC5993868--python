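"""Spike detection, rate histograms and pause/rebound/undershoot/phase metrics.

The pause/rebound quantification follows the binned scheme of the source
analysis: peri-event histograms with 20 ms bins, normalization to a baseline
rate (100 %), a centered three-bin moving average, amplitudes taken as the
extrema of the moving average, and onset/end taken from where the moving
average crosses the 100 % level.  Because a three-bin average crosses the
baseline one bin before/after the underlying rate does, the crossing times
are corrected by one bin toward the extremum so that an ideal rectangular
pause is recovered at its exact width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .simulator import VoltageTrace

__all__ = [
    "SpikeTrain",
    "RateHistogram",
    "PauseReboundStats",
    "UndershootStats",
    "detect_spikes",
    "rate_histogram",
    "pause_rebound",
    "undershoot",
    "phase_lag",
    "classify_unit",
    "rate_voltage_correlation",
    "write_spike_trains",
    "read_spike_trains",
]

DEFAULT_BIN_MS = 20.0


@dataclass
class SpikeTrain:
    """Sorted spike times (ms) of one unit in one sweep."""

    times: np.ndarray
    sweep_id: int = 0
    waveform_dur: Optional[float] = None  # ms, mean spike duration metadata

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)

    def min_isi(self) -> float:
        if self.times.size < 2:
            return math.inf
        return float(np.min(np.diff(self.times)))


@dataclass
class RateHistogram:
    """Peri-event firing-rate histogram (Hz) on a constant-width bin grid."""

    edges: np.ndarray  # ms, aligned time; length n_bins + 1
    rate: np.ndarray  # Hz
    n_sweeps: int
    baseline: float  # Hz
    baseline_window: Tuple[float, float]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        widths = np.diff(self.edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bin width must be constant")
        if np.any(self.rate < 0):
            raise ValueError("rates must be >= 0")

    @property
    def bin_ms(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class PauseReboundStats:
    """Moving-average pause/rebound summary (amplitudes in % of baseline)."""

    pause_amplitude: float
    rebound_amplitude: float
    pause_onset: Optional[float] = None
    pause_end: Optional[float] = None
    rebound_onset: Optional[float] = None
    rebound_end: Optional[float] = None

    @property
    def pause_duration(self) -> Optional[float]:
        if self.pause_onset is None or self.pause_end is None:
            return None
        return self.pause_end - self.pause_onset

    @property
    def rebound_duration(self) -> Optional[float]:
        if self.rebound_onset is None or self.rebound_end is None:
            return None
        return self.rebound_end - self.rebound_onset

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "pause_amplitude_pct": self.pause_amplitude,
            "rebound_amplitude_pct": self.rebound_amplitude,
            "pause_onset_ms": self.pause_onset,
            "pause_end_ms": self.pause_end,
            "pause_duration_ms": self.pause_duration,
            "rebound_onset_ms": self.rebound_onset,
            "rebound_end_ms": self.rebound_end,
            "rebound_duration_ms": self.rebound_duration,
        }


@dataclass
class UndershootStats:
    """Membrane-potential undershoot/overshoot summary around an input."""

    trough_depth: float  # mV below RMP, >= 0
    peak_height: float  # mV above RMP during input, >= 0
    trough_latency: float  # ms from input offset

    @property
    def trough_peak_ratio(self) -> float:
        return self.trough_depth / self.peak_height if self.peak_height > 0 else 0.0


def detect_spikes(trace: VoltageTrace, threshold: float = 0.0,
                  refractory: float = 2.0) -> SpikeTrain:
    """Upward threshold crossings, merged within the refractory window."""
    v = trace.v
    crossings = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times: List[float] = []
    for idx in crossings:
        t = float(trace.time[idx])
        if not times or t - times[-1] > refractory:
            times.append(t)
    return SpikeTrain(np.array(times))


def _resolve_align(align: Union[float, Sequence[float]], n: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(align, dtype=float))
    if arr.size == 1:
        return np.full(n, arr[0])
    if arr.size != n:
        raise ValueError("align must be scalar or one value per train")
    return arr


def rate_histogram(trains: Sequence[SpikeTrain], bin: float = DEFAULT_BIN_MS,
                   align: Union[float, Sequence[float]] = 0.0,
                   window: Optional[Tuple[float, float]] = None,
                   baseline_window: Optional[Tuple[float, float]] = None,
                   ) -> RateHistogram:
    """Event-aligned firing-rate histogram averaged over sweeps.

    ``align`` is the event time subtracted from each train (scalar or one
    per train).  ``baseline_window`` defaults to all bins ending at least
    100 ms before the event when such bins exist, otherwise the whole
    histogram.
    """
    if bin <= 0:
        raise ValueError("bin width must be > 0")
    if len(trains) == 0:
        raise ValueError("need at least one spike train")
    offsets = _resolve_align(align, len(trains))
    aligned = [tr.times - off for tr, off in zip(trains, offsets)]
    if window is None:
        non_empty = np.concatenate([a for a in aligned if a.size] or [np.array([])])
        if non_empty.size == 0:
            raise ValueError("no spikes and no explicit window")
        window = (float(non_empty.min()), float(non_empty.max()))
    lo = math.floor(window[0] / bin) * bin
    n_bins = max(1, int(math.ceil((window[1] - lo) / bin)))
    edges = lo + bin * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for a in aligned:
        c, _ = np.histogram(a, bins=edges)
        counts += c
    rate = counts / (len(trains) * bin * 1e-3)  # Hz
    if baseline_window is None:
        if edges[0] <= -100.0 - bin:
            baseline_window = (float(edges[0]), -100.0)
        else:
            baseline_window = (float(edges[0]), float(edges[-1]))
    sel = (edges[1:] > baseline_window[0]) & (edges[1:] <= baseline_window[1] + 1e-9)
    baseline = float(rate[sel].mean()) if sel.any() else float(rate.mean())
    return RateHistogram(edges, rate, len(trains), baseline, baseline_window)


def moving_average3(x: np.ndarray) -> np.ndarray:
    """Centered three-point moving average with shrinking end windows."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = x[:2].mean() if x.size > 1 else x[0]
    out[-1] = x[-2:].mean() if x.size > 1 else x[-1]
    return out


def _crossing_bounds(ma: np.ndarray, i_ext: int, below: bool,
                     edges: np.ndarray) -> Tuple[Optional[float], Optional[float]]:
    """Onset/end of the excursion containing bin ``i_ext``.

    The excursion is the maximal run of moving-average bins on the extremum
    side of 100 %; crossings are corrected one bin inward to undo the
    half-window smearing of the three-bin average.  A side without any
    crossing inside the histogram is reported as None (undefined).
    """
    sign = -1.0 if below else 1.0
    off = sign * (ma - 100.0) > 0  # True where on the extremum side
    i0 = i_ext
    while i0 > 0 and off[i0 - 1]:
        i0 -= 1
    i1 = i_ext
    while i1 < off.size - 1 and off[i1 + 1]:
        i1 += 1
    onset = float(edges[i0 + 1]) if i0 > 0 else None
    end = float(edges[i1]) if i1 < off.size - 1 else None
    if onset is not None and end is not None and not onset < end:
        return None, None
    return onset, end


def pause_rebound(hist: RateHistogram) -> PauseReboundStats:
    """Pause/rebound amplitudes and timing from the normalized moving average.

    Rates are normalized to baseline = 100 %; the pause (rebound) amplitude
    is the minimum (maximum) of the centered three-bin moving average, and
    onset/end are the corrected baseline crossings bracketing each extremum
    (None when the moving average never returns across baseline).
    """
    if hist.baseline <= 0:
        raise ValueError("baseline rate must be > 0")
    norm = hist.rate / hist.baseline * 100.0
    ma = moving_average3(norm)
    i_min = int(np.argmin(ma))
    i_max = int(np.argmax(ma))
    pause_amp = float(ma[i_min])
    rebound_amp = float(ma[i_max])
    p_on = p_end = r_on = r_end = None
    if pause_amp < 100.0:
        p_on, p_end = _crossing_bounds(ma, i_min, below=True, edges=hist.edges)
    if rebound_amp > 100.0:
        r_on, r_end = _crossing_bounds(ma, i_max, below=False, edges=hist.edges)
    return PauseReboundStats(pause_amp, rebound_amp, p_on, p_end, r_on, r_end)


def undershoot(trace: VoltageTrace, rmp: float,
               input_epochs: Dict[str, Tuple[float, float]],
               ) -> UndershootStats:
    """Trough/peak of a (spike-free) voltage trace around an input window.

    The input window spans the named epochs; the trough is the largest
    excursion below ``rmp`` after the input offset, the peak the largest
    excursion above ``rmp`` during the input.
    """
    if not input_epochs:
        raise ValueError("input_epochs must name at least one epoch")
    onset = min(a for a, _ in input_epochs.values())
    offset = max(b for _, b in input_epochs.values())
    t = trace.time
    after = t >= offset
    during = (t >= onset) & (t <= offset)
    if not after.any() or not during.any():
        raise ValueError("trace does not cover the annotated input window")
    v_after = trace.v[after]
    t_after = t[after]
    i_tr = int(np.argmin(v_after))
    trough = max(0.0, rmp - float(v_after[i_tr]))
    peak = max(0.0, float(trace.v[during].max()) - rmp)
    latency = float(t_after[i_tr] - offset) if trough > 0 else 0.0
    return UndershootStats(trough, peak, latency)


def _first_harmonic_phase(hist: RateHistogram, ref_freq: float) -> float:
    """Phase (radians) of the rate profile's component at ``ref_freq``,
    with the profile modeled as cos(2 pi f t - phase)."""
    t = hist.centers * 1e-3  # s
    r = hist.rate - hist.rate.mean()
    w = 2.0 * math.pi * ref_freq
    s = float(np.sum(r * np.sin(w * t)))
    c = float(np.sum(r * np.cos(w * t)))
    power = math.hypot(s, c)
    if power <= 1e-12 * max(1.0, float(np.abs(r).sum())):
        raise ValueError("profile has no power at the reference frequency")
    return math.atan2(s, c)


def phase_lag(rate_a: RateHistogram, rate_b: RateHistogram,
              ref_freq: float) -> float:
    """Phase of ``rate_b`` minus ``rate_a`` at ``ref_freq`` in degrees,
    wrapped to (-180, 180].  Positive means b lags (peaks later than) a."""
    if ref_freq <= 0:
        raise ValueError("ref_freq must be > 0")
    if abs(rate_a.bin_ms - rate_b.bin_ms) > 1e-9:
        raise ValueError("histograms must share the same binning")
    dphi = _first_harmonic_phase(rate_b, ref_freq) - _first_harmonic_phase(rate_a, ref_freq)
    deg = math.degrees(dphi)
    deg = (deg + 180.0) % 360.0 - 180.0
    if deg == -180.0:
        deg = 180.0
    return deg


def classify_unit(rate: float, waveform_dur: float, min_isi: float,
                  tonic_range: Tuple[float, float] = (3.0, 10.0),
                  ) -> str:
    """Classify a unit from rate (Hz), spike duration (ms) and min ISI (ms).

    Broad spikes (> 1.1 ms) with tonic 3-10 Hz firing and min ISI > 20 ms
    are putative ChIs; broad spikes below 1 Hz are SPNs; short spikes are
    FSIs; tonic units with min ISI < 10 ms (bursty) are LTS neurons.
    """
    for value in (rate, waveform_dur, min_isi):
        if not math.isfinite(value) and value != math.inf:
            raise ValueError("inputs must be finite")
    broad = waveform_dur > 1.1
    if not broad:
        return "FSI"
    if rate < 1.0:
        return "SPN"
    tonic = tonic_range[0] <= rate <= tonic_range[1]
    if tonic and min_isi > 20.0:
        return "pChI"
    if tonic and min_isi < 10.0:
        return "LTS"
    return "unclassified"


def rate_voltage_correlation(rate: RateHistogram, v: VoltageTrace,
                             n_bins: int = 100) -> float:
    """Squared Pearson correlation between binned mean voltage and rate."""
    t0 = max(float(rate.edges[0]), float(v.time[0]))
    t1 = min(float(rate.edges[-1]), float(v.time[-1]))
    if t1 <= t0:
        raise ValueError("no overlapping time support")
    edges = np.linspace(t0, t1, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, v.time, side="right") - 1, 0, n_bins - 1)
    sel = (v.time >= t0) & (v.time <= t1)
    mean_v = np.bincount(idx[sel], weights=v.v[sel], minlength=n_bins)
    counts = np.bincount(idx[sel], minlength=n_bins)
    valid = counts > 0
    mean_v = mean_v[valid] / counts[valid]
    centers = 0.5 * (edges[:-1] + edges[1:])[valid]
    r_interp = np.interp(centers, rate.centers, rate.rate)
    if np.ptp(mean_v) == 0 or np.ptp(r_interp) == 0:
        raise ValueError("constant input: correlation undefined")
    r, _ = stats.pearsonr(mean_v, r_interp)
    return float(r * r)


# ---------------------------------------------------------------------------
# delimited-text spike-train IO


def write_spike_trains(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    rows = [(tr.sweep_id, t) for tr in trains for t in tr.times]
    with open(path, "w") as fh:
        fh.write("sweep_id\tspike_time_ms\n")
        for sweep, t in rows:
            fh.write(f"{sweep}\t{t:.6f}\n")


def read_spike_trains(path: str | Path) -> List[SpikeTrain]:
    sweeps: Dict[int, List[float]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            sweep, t = line.split()
            sweeps.setdefault(int(sweep), []).append(float(t))
    return [SpikeTrain(np.array(sorted(ts)), sweep_id=sweep)
            for sweep, ts in sorted(sweeps.items())]
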