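# chipause

Single-compartment model of a striatal cholinergic interneuron (ChI) whose
slow, non-inactivating delayed-rectifier K⁺ current (`kr`, Kv7-like) turns
receding excitatory input into a membrane-potential undershoot — the
subthreshold correlate of the ChI "pause" — together with the stimulus
protocols, dopamine-D₂-current interactions, and the pause/rebound/phase
quantification pipeline used to characterize it.

## What's inside

| module | contents |
| --- | --- |
| `chipause.channels` | Boltzmann gating, voltage-dependent time constants, per-channel current densities (leak + fast inactivating A-current + slow rectifier) |
| `chipause.simulator` | exponential-Euler membrane integrator, current-clamp and voltage-step protocols, resting-potential calibration, in-silico pharmacology (XE-991/TEA, 4-AP, Zd7288 ± RMP restoration) |
| `chipause.stimuli` | sine / trapezoid / step waveform builders, D₂-current shape (quarter-sine rise, linear or exponential decay), waveform composition, the −13.6 pA Ohm's-law undershoot mimic |
| `chipause.metrics` | spike detection, 20 ms peri-event rate histograms, moving-average pause/rebound statistics, membrane-potential undershoot statistics, first-harmonic phase lag, unit classification, rate–voltage correlation |
| `chipause.synthetic` | seeded generator of in-vivo-like recordings: ~1 Hz inverted-LFP oscillation, a tonic unit driven by its derivative, a lagging SPN-like unit, inhomogeneous-Poisson spikes with refractory period, pause-scenario fixtures |
| `chipause.scenarios` | named end-to-end scenarios (`fig4a` … `fig4h`, `s2a_mimic`, `small_withdrawal`, `invivo_phase`) defined as data in `chipause/data/scenarios.yaml`, plus a threshold-checked report |
| `chipause.cli` | `chipause` command with `simulate`, `analyze`, `synth`, `scenario`, `report` subcommands |

Model parameters live in a versioned config file
(`src/chipause/data/model_default.yaml`): geometry (15 × 40 µm cylinder,
1 µF/cm²), leak 0.09 mS/cm², maximal conductances 2 / 0.5 mS/cm², K⁺
reversal −85 mV, target resting potentials −40 / −76 mV, plus the gating
kinetics (package defaults — see the comments in that file) and the D₂ and
synthetic-recording defaults. Every value can be overridden by passing your
own YAML via `--config`.

## CLI examples

```bash
# run a named scenario and write traces, metrics and a manifest
chipause scenario --scenario fig4b --out out/fig4b

# trapezoid current clamp with the default model
chipause simulate --trapezoid 100 --out trace.tsv

# synthetic in-vivo-like recording, then pause/rebound metrics
chipause synth --seed 1 --out rec/
chipause analyze --spikes rec/chi_spikes.tsv --window 0,20000

# collate scenario metrics against the shipped thresholds
chipause report --results out/fig4b
```

## Conventions

Outward membrane current and depolarizing injected current are positive;
voltages in mV, time in ms, conductance densities in mS/cm², current
densities in µA/cm², somatic currents in pA (converted through the membrane
area). Traces, waveforms and spike trains are read and written as
tab-separated text.
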