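# Pass/fail bounds applied by the `report` command to scenario metrics.
version: 1

thresholds:
  fig4a:
    kr_sag_fraction: {op: "<", value: 0.02}
    a_inactivation_fraction: {op: ">", value: 0.9}
  fig4b:
    undershoot_mV_full: {op: ">=", value: 1.0}
    undershoot_mV_kr_only: {op: ">=", value: 1.0}
    undershoot_mV_a_only: {op: "<", value: 0.2}
    undershoot_mV_leak_only: {op: "<", value: 0.2}
  fig4c:
    kr_lag_ms: {op: ">", value: 0.0}
  fig4d:
    undershoot_loss_fraction: {op: ">=", value: 0.8}
    undershoot_restored_fraction: {op: ">=", value: 0.7}
  fig4e:
    trough_monotone: {op: "==", value: 1.0}
    latency_range_ms: {op: "<", value: 20.0}
  fig4f:
    trough_deepening_mV: {op: ">", value: 0.0}
  fig4g:
    trough_change_frac: {op: "<", value: 0.1}
    rebound_reduction_mV: {op: ">", value: 0.0}
  fig4h:
    trough_monotone: {op: "==", value: 1.0}
  s2a_mimic:
    amplitude_pA: {op: "~=", value: -13.6, tol: 1.0e-9}
  small_withdrawal:
    undershoot_mV: {op: ">", value: 0.5}
  invivo_phase:
    spn_chi_lag_deg: {op: "~=", value: 60.0, tol: 5.0}
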