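import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipause.metrics import (RateHistogram, SpikeTrain, classify_unit,
                              detect_spikes, moving_average3, pause_rebound,
                              phase_lag, rate_histogram,
                              rate_voltage_correlation, read_spike_trains,
                              undershoot, write_spike_trains)
from chipause.simulator import VoltageTrace
from chipause.synthetic import RateProfile, RecordingSpec, sample_spikes


def make_trace(time, v):
    time = np.asarray(time, dtype=float)
    return VoltageTrace(time, np.asarray(v, dtype=float), np.zeros_like(time))


def hist_from_rates(rates, bin_ms=20.0, baseline=None, t0=0.0):
    rates = np.asarray(rates, dtype=float)
    edges = t0 + bin_ms * np.arange(rates.size + 1)
    if baseline is None:
        baseline = rates.mean()
    return RateHistogram(edges, rates, n_sweeps=1, baseline=float(baseline),
                         baseline_window=(t0, t0 + bin_ms))


class TestDetectSpikes:
    def test_subthreshold_trace_is_empty(self):
        t = np.arange(0, 100, 0.1)
        trace = make_trace(t, -50 + 5 * np.sin(t))
        assert detect_spikes(trace).n == 0

    def test_counts_well_separated_crossings(self):
        t = np.arange(0, 100, 0.1)
        v = np.full(t.size, -60.0)
        for t_spike in (10.0, 40.0, 70.0):
            v[np.abs(t - t_spike) < 0.5] = 20.0
        assert detect_spikes(make_trace(t, v)).n == 3

    def test_refractory_merging(self):
        t = np.arange(0, 10, 0.1)
        v = np.full(t.size, -60.0)
        v[np.abs(t - 3.0) < 0.15] = 20.0
        v[np.abs(t - 4.0) < 0.15] = 20.0  # 1 ms later
        assert detect_spikes(make_trace(t, v), refractory=2.0).n == 1
        assert detect_spikes(make_trace(t, v), refractory=0.5).n == 2


class TestRateHistogram:
    def test_empty_trains_give_zero_histogram(self):
        trains = [SpikeTrain(np.empty(0), sweep_id=i) for i in range(5)]
        hist = rate_histogram(trains, bin=20.0, window=(0.0, 200.0))
        assert np.all(hist.rate == 0.0)

    def test_single_bin_rate_is_50hz(self):
        # one spike per sweep in one 20 ms bin -> 1 / 0.02 s = 50 Hz
        trains = [SpikeTrain(np.array([130.0]), sweep_id=i) for i in range(10)]
        hist = rate_histogram(trains, bin=20.0, window=(0.0, 200.0))
        k = np.searchsorted(hist.edges, 130.0) - 1
        assert hist.rate[k] == pytest.approx(50.0)
        assert hist.rate.sum() == pytest.approx(50.0)

    def test_homogeneous_poisson_mean_rate(self):
        spec = RecordingSpec(duration_ms=10_000.0, refractory=0.0, seed=42)
        profile = RateProfile(np.arange(0, 10_001.0), np.full(10_001, 5.0))
        trains = sample_spikes(profile, spec, n_sweeps=200)
        hist = rate_histogram(trains, bin=20.0, window=(0.0, 10_000.0))
        se = math.sqrt(5.0 / (200 * 10.0))  # Poisson SE of the mean rate
        assert abs(hist.rate.mean() - 5.0) < 3 * se

    def test_alignment_shifts_spikes(self):
        trains = [SpikeTrain(np.array([500.0])), SpikeTrain(np.array([520.0]))]
        hist = rate_histogram(trains, bin=20.0, align=[500.0, 520.0],
                              window=(-100.0, 100.0))
        k = np.searchsorted(hist.edges, 0.0)
        assert hist.rate[k] == pytest.approx(50.0)

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            rate_histogram([SpikeTrain(np.array([1.0]))], bin=0.0)

    def test_baseline_from_pre_event_window(self):
        rng = np.random.default_rng(0)
        trains = [SpikeTrain(np.sort(rng.uniform(-1000, 0, 10))) for _ in range(50)]
        hist = rate_histogram(trains, bin=20.0, window=(-1000.0, 500.0))
        assert hist.baseline == pytest.approx(10.0, rel=0.2)


class TestPauseRebound:
    def test_flat_histogram(self):
        stats = pause_rebound(hist_from_rates(np.full(50, 8.0)))
        assert stats.pause_amplitude == pytest.approx(100.0)
        assert stats.pause_onset is None and stats.pause_end is None

    def test_three_bin_dip_recovered(self):
        rates = np.full(50, 10.0)
        rates[20:23] = 4.0  # 40 % of baseline for 3 bins
        stats = pause_rebound(hist_from_rates(rates, baseline=10.0))
        assert stats.pause_amplitude == pytest.approx(40.0)
        assert abs(stats.pause_duration - 60.0) <= 20.0
        assert abs(stats.pause_onset - 400.0) <= 20.0

    def test_ten_bin_dip_exact(self):
        rates = np.full(60, 10.0)
        rates[25:35] = 4.0
        stats = pause_rebound(hist_from_rates(rates, baseline=10.0))
        assert stats.pause_amplitude == pytest.approx(40.0)
        assert stats.pause_duration == pytest.approx(200.0)

    def test_dip_then_peak_ordering(self):
        rates = np.full(60, 10.0)
        rates[20:26] = 3.0
        rates[30:36] = 18.0
        stats = pause_rebound(hist_from_rates(rates, baseline=10.0))
        assert stats.pause_amplitude < 100.0 < stats.rebound_amplitude
        assert stats.pause_end <= stats.rebound_onset
        assert stats.pause_amplitude <= 100.0 <= stats.rebound_amplitude

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            pause_rebound(hist_from_rates(np.zeros(10), baseline=0.0))

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_uniform_rescaling(self, scale):
        rates = np.full(40, 10.0)
        rates[15:20] = 4.0
        a = pause_rebound(hist_from_rates(rates, baseline=10.0))
        b = pause_rebound(hist_from_rates(rates * scale, baseline=10.0 * scale))
        assert b.pause_amplitude == pytest.approx(a.pause_amplitude)
        assert b.pause_duration == a.pause_duration

    def test_moving_average_edges_shrink(self):
        x = np.array([3.0, 6.0, 9.0])
        ma = moving_average3(x)
        assert ma[0] == pytest.approx(4.5)
        assert ma[1] == pytest.approx(6.0)
        assert ma[2] == pytest.approx(7.5)


class TestUndershoot:
    def test_monotone_return_has_zero_trough(self):
        t = np.arange(0, 1000.0, 1.0)
        v = -40.0 + 10.0 * np.exp(-np.maximum(0, t - 500.0) / 100.0) * (t >= 500.0)
        v[t < 500.0] = -30.0
        stats = undershoot(make_trace(t, v), -40.0, {"input": (0.0, 500.0)})
        assert stats.trough_depth == 0.0
        assert stats.trough_peak_ratio == 0.0

    def test_constructed_dip_of_2p72_mv(self):
        t = np.arange(0, 1000.0, 1.0)
        v = np.full(t.size, -40.0)
        v[(t >= 0) & (t <= 300)] = -35.0
        dip = (t > 400) & (t < 600)
        v[dip] = -40.0 - 2.72 * np.sin(math.pi * (t[dip] - 400) / 200.0)
        stats = undershoot(make_trace(t, v), -40.0, {"input": (0.0, 300.0)})
        assert stats.trough_depth == pytest.approx(2.72, abs=1e-6)
        assert stats.peak_height == pytest.approx(5.0)

    def test_scaling_preserves_ratio(self):
        t = np.arange(0, 1000.0, 1.0)
        dv = np.zeros(t.size)
        dv[(t >= 100) & (t <= 400)] = 6.0
        dv[(t > 500) & (t < 700)] = -3.0
        base = undershoot(make_trace(t, -40.0 + dv), -40.0, {"in": (100.0, 400.0)})
        doubled = undershoot(make_trace(t, -40.0 + 2 * dv), -40.0,
                             {"in": (100.0, 400.0)})
        assert doubled.trough_depth == pytest.approx(2 * base.trough_depth)
        assert doubled.peak_height == pytest.approx(2 * base.peak_height)
        assert doubled.trough_peak_ratio == pytest.approx(base.trough_peak_ratio)

    def test_missing_annotation_rejected(self):
        t = np.arange(0, 100.0, 1.0)
        with pytest.raises(ValueError):
            undershoot(make_trace(t, np.full(t.size, -40.0)), -40.0, {})


class TestPhaseLag:
    @staticmethod
    def sin_hist(phase_deg, freq=1.0, n_bins=500, bin_ms=20.0):
        centers = bin_ms * (np.arange(n_bins) + 0.5)
        rate = 5.0 + 2.0 * np.cos(2 * math.pi * freq * centers * 1e-3
                                  - math.radians(phase_deg))
        return hist_from_rates(rate, bin_ms=bin_ms)

    def test_identical_profiles(self):
        h = self.sin_hist(0.0)
        assert phase_lag(h, h, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_quarter_period_shift_is_90_degrees(self):
        assert phase_lag(self.sin_hist(0.0), self.sin_hist(90.0), 1.0) == (
            pytest.approx(90.0, abs=2.0))

    def test_antiphase_is_180_degrees(self):
        lag = phase_lag(self.sin_hist(0.0), self.sin_hist(180.0), 1.0)
        assert abs(lag) == pytest.approx(180.0, abs=2.0)

    @given(st.floats(-170, 170), st.floats(-170, 170))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry(self, p1, p2):
        a, b = self.sin_hist(p1), self.sin_hist(p2)
        fwd = phase_lag(a, b, 1.0)
        rev = phase_lag(b, a, 1.0)
        total = abs(fwd + rev) % 360.0
        assert min(total, 360.0 - total) < 1e-6

    def test_zero_power_profile_rejected(self):
        flat = hist_from_rates(np.full(100, 5.0))
        with pytest.raises(ValueError):
            phase_lag(flat, flat, 1.0)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            phase_lag(self.sin_hist(0.0, bin_ms=20.0),
                      self.sin_hist(0.0, bin_ms=10.0), 1.0)


class TestClassifyUnit:
    @pytest.mark.parametrize("rate,dur,isi,label", [
        (5.0, 1.3, 30.0, "pChI"),
        (0.4, 1.3, 500.0, "SPN"),
        (5.0, 1.3, 8.0, "LTS"),
        (20.0, 0.5, 3.0, "FSI"),
        (15.0, 1.3, 30.0, "unclassified"),
    ])
    def test_rules(self, rate, dur, isi, label):
        assert classify_unit(rate, dur, isi) == label

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_unit(float("nan"), 1.3, 30.0)


class TestRateVoltageCorrelation:
    def test_rate_proportional_to_voltage(self):
        t = np.arange(0, 2000.0, 1.0)
        v = -50.0 + 10.0 * np.sin(2 * math.pi * t / 1000.0)
        trace = make_trace(t, v)
        edges = np.arange(0.0, 2001.0, 20.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rate = 5.0 + np.interp(centers, t, v - v.mean())
        hist = RateHistogram(edges, rate - rate.min() + 1.0, 1, 5.0, (0.0, 100.0))
        assert rate_voltage_correlation(hist, trace, n_bins=100) > 0.99

    def test_sign_blind(self):
        t = np.arange(0, 2000.0, 1.0)
        v = -50.0 + 10.0 * np.sin(2 * math.pi * t / 1000.0)
        trace = make_trace(t, v)
        edges = np.arange(0.0, 2001.0, 20.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rate = 50.0 - np.interp(centers, t, v - v.mean())
        hist = RateHistogram(edges, rate, 1, 5.0, (0.0, 100.0))
        assert rate_voltage_correlation(hist, trace, n_bins=100) > 0.99

    def test_independent_noise_has_low_r2(self):
        # null distribution: independent white-noise pairs rarely exceed 0.1
        low = 0
        n_seeds = 40
        t = np.arange(0, 2000.0, 1.0)
        edges = np.arange(0.0, 2001.0, 20.0)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            trace = make_trace(t, -50 + rng.normal(0, 3, t.size))
            hist = RateHistogram(edges, 5 + rng.uniform(0, 2, 100), 1, 5.0,
                                 (0.0, 100.0))
            if rate_voltage_correlation(hist, trace, n_bins=100) < 0.1:
                low += 1
        assert low >= int(0.9 * n_seeds)

    def test_constant_input_rejected(self):
        t = np.arange(0, 2000.0, 1.0)
        trace = make_trace(t, np.full(t.size, -40.0))
        edges = np.arange(0.0, 2001.0, 20.0)
        hist = RateHistogram(edges, np.full(100, 5.0), 1, 5.0, (0.0, 100.0))
        with pytest.raises(ValueError):
            rate_voltage_correlation(hist, trace)


class TestSpikeTrainIO:
    def test_roundtrip(self, tmp_path):
        trains = [SpikeTrain(np.array([10.0, 55.5, 200.25]), sweep_id=0),
                  SpikeTrain(np.array([5.0]), sweep_id=1),
                  SpikeTrain(np.empty(0), sweep_id=2)]
        path = tmp_path / "spikes.tsv"
        write_spike_trains(trains, path)
        back = read_spike_trains(path)
        assert len(back) == 2  # empty sweeps have no rows
        assert np.allclose(back[0].times, trains[0].times)

    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([10.0, 10.0]))

    def test_min_isi(self):
        assert SpikeTrain(np.array([0.0, 25.0, 90.0])).min_isi() == 25.0
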