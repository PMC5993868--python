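# Named end-to-end scenarios (data, not code): each entry gives the
# protocol kind plus its parameters.  Currents in pA, durations in ms.
version: 1

scenarios:
  fig4a:
    kind: vclamp
    description: Voltage-step families of the two K+ conductances
    holding_mV: -100.0
    step_mV: 20.0
    n_steps: 5
    step_dur_ms: 4000.0

  fig4b:
    kind: trapezoid_variants
    description: Trapezoid response with leak and rectifier and/or A-current
    peak_pA: 100.0
    ramp_up_ms: 4000.0
    plateau_ms: 4000.0
    ramp_down_ms: 4000.0
    tail_ms: 3000.0
    variants:
      full: [a, kr]
      kr_only: [kr]
      a_only: [a]
      leak_only: []

  fig4c:
    kind: current_lag
    description: Rectifier current-density extremum lags the injected ramp
    peak_pA: 100.0
    ramp_up_ms: 4000.0
    plateau_ms: 4000.0
    ramp_down_ms: 4000.0
    tail_ms: 3000.0

  fig4d:
    kind: rmp_dependence
    description: Undershoot lost at hyperpolarized RMP, restored with depolarization
    peak_pA: 100.0
    ramp_up_ms: 4000.0
    plateau_ms: 4000.0
    ramp_down_ms: 4000.0
    tail_ms: 3000.0
    variants: [control, zd7288, zd7288_restored]

  fig4e:
    kind: sine_family
    description: Short sine input; trough scales with amplitude, latency does not
    amplitudes_pA: [25.0, 50.0, 75.0, 100.0]
    freq_hz: 2.0
    duration_ms: 500.0
    tail_ms: 2000.0

  fig4f:
    kind: d2_summation
    description: D2 current and rectifier after separate and combined activation
    bump: {peak_pA: 50.0, ramp_up_ms: 100.0, plateau_ms: 200.0, ramp_down_ms: 100.0}
    d2_override: {decay_dur_ms: 800.0}
    tail_ms: 3200.0

  fig4g:
    kind: d2_timing
    description: D2 timed at pause onset, with and without rebound input
    bump: {peak_pA: 75.0, ramp_up_ms: 150.0, plateau_ms: 200.0, ramp_down_ms: 150.0}
    rebound: {peak_pA: 50.0, ramp_up_ms: 100.0, plateau_ms: 200.0, ramp_down_ms: 100.0,
              onset_ms: 800.0}
    d2_shift_ms: 500.0   # pause onset = end of the excitatory bump
    total_ms: 2500.0
    trough_window_ms: [500.0, 800.0]
    rebound_window_ms: [800.0, 1600.0]

  fig4h:
    kind: learning_scaling
    description: Enhanced excitatory input (learning) scales the undershoot
    excitatory_scales: [1.0, 1.5, 2.0]
    bump: {peak_pA: 75.0, ramp_up_ms: 150.0, plateau_ms: 200.0, ramp_down_ms: 150.0}
    rebound: {peak_pA: 50.0, ramp_up_ms: 100.0, plateau_ms: 200.0, ramp_down_ms: 100.0,
              onset_ms: 800.0}
    d2_shift_ms: 500.0
    total_ms: 2500.0
    trough_window_ms: [500.0, 800.0]

  s2a_mimic:
    kind: undershoot_mimic
    description: Negative current mimicking the rectifier undershoot (Ohm's law)
    r_in_MOhm: 200.0
    v_target_mV: 2.72
    tail_ms: 1000.0

  small_withdrawal:
    kind: small_withdrawal
    description: Withdrawal of a 25 pA excitatory half-sine input
    amplitude_pA: 25.0
    freq_hz: 2.0
    duration_ms: 250.0
    tail_ms: 2000.0

  invivo_phase:
    kind: invivo_phase
    description: Recover the SPN-vs-ChI phase lag from synthetic recordings
    bin_ms: 20.0
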