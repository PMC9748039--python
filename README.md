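# voltstim

Single-neuron voltage-imaging analysis of deep brain stimulation (DBS).

High-speed fluorescence voltage indicators (e.g. SomArchon, imaged at
~828 frames/s) report both action potentials and subthreshold membrane
voltage (Vm) of individual neurons, and — unlike electrophysiology — are
immune to electrical stimulation artifacts. `voltstim` implements the
analysis chain needed to ask how DBS pulse trains reshape a neuron's
activity: rigid motion correction and ROI trace extraction, photobleach
detrending that excludes the stimulation window, adaptive-threshold spike
detection with the spike-to-baseline ratio (SBR), reconstruction of Vm in
spike-amplitude units, stimulus-triggered averaging, time–frequency power,
and spike–Vm phase locking with bootstrap and permutation inference.

Because raw recordings of this kind are rarely deposited, the package ships
a first-class synthetic-data generator that emulates the study design —
trial-structured traces and movies with theta-band (3–12 Hz) subthreshold
oscillations, pulse-locked depolarization kernels at 40 or 140 Hz, 8 Hz
optogenetic drive with a soft voltage ceiling, spikes riding on Vm,
photobleaching, shot-like noise and frame-to-frame motion — with full
ground truth, so every stage of the pipeline is verifiable end to end.

## The statistics at the core

* **SBR** — mean spike amplitude divided by the SD of the spike-removed
  trace; spike amplitude is the peak fluorescence minus the minimum of the
  three frames before the peak.
* **Vm** — the spike-removed, detrended trace divided by the neuron's mean
  spike amplitude, optionally re-referenced per trial to the 1 s
  pre-stimulation baseline. Quantification windows: transient 0–0.15 s and
  sustained 0.15–1 s from stimulation onset.
* **Phase-locking value** — for spike phases φ(f, n) read from the
  band-passed (order-2 Butterworth, ±2 Hz) Hilbert phase of Vm,

  PLV(f) = | (1/N) Σₙ exp(i φ(f, n)) | ∈ [0, 1],

  with bootstrap SD over spike resamples and a permutation null that
  redraws spike times uniformly within the analysis window.

## Worked example

```python
import voltstim as vs

cfg = vs.dbs_scenario(40.0, n_trials=8, target_sbr=7.0, seed=21,
                      spike_mode="poisson")
protocol = vs.generate_protocol(cfg)
truth = vs.generate_vm_and_spikes(cfg, protocol)
trace = vs.render_trace(truth, cfg, protocol)

detrended = vs.detrend_trace(trace, protocol)
spikes = vs.detect_spikes(detrended)
sbr = vs.compute_sbr(detrended, spikes)
vm = vs.baseline_normalize(
    vs.normalize_vm(vs.remove_spikes(detrended, spikes),
                    spikes.mean_amplitude()),
    protocol)
stats = vs.window_stats(vm, protocol)
```

Output for this seed:

```
spikes detected: 173  (ground truth: 173)
SBR: 7.31
Vm change vs baseline  transient: +0.199  sustained: +0.135  post: -0.020
40 Hz Vm power, stim/baseline: 18.6x
```

Read: every ground-truth spike was recovered; the neuron's spikes stand
7.3 baseline-SDs tall; 40 Hz stimulation depolarizes Vm by ~0.2 spike
amplitudes early and ~0.14 in the sustained window, returning to baseline
after offset; Vm power at the stimulation frequency rises ~19-fold during
the train — the entrainment signature.

## Command line

Each pipeline stage is a subcommand of the `voltstim` console script:

```bash
voltstim simulate --out session/ --seed 4 --movie
voltstim register --in session/movie.tif --out session/reg/
voltstim extract --movie session/reg/registered.tif --mask mask.json --out trace.csv
voltstim preprocess --trace trace.csv --protocol session/protocol.json --out detrended.csv
voltstim detect --trace detrended.csv --out spikes/
voltstim analyze --trace trace.csv --protocol session/protocol.json --out analysis/
voltstim report --config run.yaml --out report/
```

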