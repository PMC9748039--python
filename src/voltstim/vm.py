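"""Subthreshold membrane-voltage (Vm) reconstruction and quantification.

Vm is the spike-removed fluorescence trace expressed in units of the
neuron's mean spike amplitude, optionally re-referenced per trial to the 1 s
pre-stimulation baseline. Firing rate is a frame-resolution indicator series
smoothed with a unit-area rectangular kernel. The quantification windows
follow the study design: transient 0-0.15 s and sustained 0.15-1 s from
stimulation onset, 1 s pre-onset baseline, and a matched 1 s post-offset
window.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np

from .containers import (FluorescenceTrace, RateTrace, SpikeTrain, StimProtocol,
                         VmTrace, WindowStats)

__all__ = [
    "remove_spikes",
    "normalize_vm",
    "baseline_normalize",
    "firing_rate",
    "window_stats",
    "trial_matrix",
]

TRANSIENT_WINDOW = (0.0, 0.15)
SUSTAINED_WINDOW = (0.15, 1.0)
BASELINE_DURATION = 1.0
POST_DURATION = 1.0


def remove_spikes(trace: FluorescenceTrace, spikes: SpikeTrain) -> FluorescenceTrace:
    """Replace the 3 frames centered on each spike peak by linear interpolation.

    Overlapping removal windows merge into one gap; gaps are interpolated
    between the nearest untouched neighbors (one-sided fill at trace edges).
    Applying the same removal twice is an identity on the second pass.
    """
    values = trace.values.copy()
    n = values.size
    if spikes.n_spikes == 0:
        return trace.with_values(values)
    removed = np.zeros(n, dtype=bool)
    for pk in spikes.spike_frames:
        removed[max(pk - 1, 0):min(pk + 2, n)] = True
    keep = np.flatnonzero(~removed)
    if keep.size == 0:
        raise ValueError("spike removal would delete the entire trace")
    gaps = np.flatnonzero(removed)
    values[gaps] = np.interp(gaps, keep, values[keep])
    return trace.with_values(values)


def normalize_vm(spike_removed: FluorescenceTrace,
                 mean_spike_amplitude: Optional[float]) -> VmTrace:
    """Express the spike-removed trace in units of the mean spike amplitude.

    Without spikes there is no amplitude unit; the trace is passed through in
    raw units and flagged non-comparable across neurons.
    """
    if mean_spike_amplitude is None or not np.isfinite(mean_spike_amplitude):
        warnings.warn("no spike amplitude available; Vm left in raw units "
                      "(not comparable across neurons)")
        return VmTrace(values=spike_removed.values,
                       sampling_rate=spike_removed.sampling_rate,
                       trial_boundaries=spike_removed.trial_boundaries,
                       normalization="raw_units",
                       protocol=spike_removed.protocol)
    if mean_spike_amplitude <= 0:
        raise ValueError("mean spike amplitude must be positive")
    return VmTrace(values=spike_removed.values / mean_spike_amplitude,
                   sampling_rate=spike_removed.sampling_rate,
                   trial_boundaries=spike_removed.trial_boundaries,
                   normalization="none",
                   protocol=spike_removed.protocol)


def _per_trial_windows(protocol: StimProtocol, fs: float, n: int):
    """Frame ranges (baseline, transient, sustained, post) per trial."""
    out = []
    for t0 in protocol.trial_starts():
        onset = t0 + protocol.dbs_window[0]
        offset = t0 + protocol.dbs_window[1]
        trial_end = t0 + protocol.trial_duration

        def rng(a, b):
            i0 = max(int(round(a * fs)), 0)
            i1 = min(int(round(b * fs)), n)
            return (i0, i1) if i1 > i0 else None

        out.append({
            "baseline": rng(max(onset - BASELINE_DURATION, t0), onset),
            "transient": rng(onset + TRANSIENT_WINDOW[0], onset + TRANSIENT_WINDOW[1]),
            "sustained": rng(onset + SUSTAINED_WINDOW[0], onset + SUSTAINED_WINDOW[1]),
            "post": rng(offset, min(offset + POST_DURATION, trial_end)),
        })
    return out


def baseline_normalize(vm: VmTrace, protocol: StimProtocol) -> VmTrace:
    """Subtract each trial's mean Vm over the 1 s before stimulation onset."""
    fs = vm.sampling_rate
    values = vm.values.copy()
    n = values.size
    starts = protocol.trial_boundaries(fs)
    stops = np.append(starts[1:], n)
    for windows, t0, t1 in zip(_per_trial_windows(protocol, fs, n), starts, stops):
        base = windows["baseline"]
        if base is None:
            warnings.warn("trial lacks a baseline window; left unnormalized")
            continue
        i0, i1 = base
        if i1 - i0 < int(BASELINE_DURATION * fs):
            warnings.warn("baseline window truncated; using available frames")
        values[t0:t1] -= values[i0:i1].mean()
    return vm.with_values(values, normalization="baseline_subtracted")


def firing_rate(spikes: SpikeTrain, n_frames: int, sampling_rate: float,
                smoothing_window: float = 0.025,
                trial_boundaries=None) -> RateTrace:
    """Frame-resolution rate: spike indicator × rate, boxcar smoothed.

    The kernel has unit area so the smoothed rate integrates to the spike
    count (up to edge loss for spikes within half a window of the ends).
    """
    width = max(1, int(round(smoothing_window * sampling_rate)))
    indicator = np.zeros(n_frames)
    inside = spikes.spike_frames[(spikes.spike_frames >= 0)
                                 & (spikes.spike_frames < n_frames)]
    indicator[inside] = sampling_rate
    kernel = np.ones(width) / width
    values = np.convolve(indicator, kernel, mode="same")
    if trial_boundaries is None:
        trial_boundaries = np.zeros(1, dtype=int)
    return RateTrace(values=values, sampling_rate=sampling_rate,
                     smoothing_window=width / sampling_rate,
                     trial_boundaries=trial_boundaries)


def window_stats(sig: Union[VmTrace, RateTrace],
                 protocol: StimProtocol) -> WindowStats:
    """Trial means of the signal in the quantification windows.

    Per-trial means are computed first and averaged across trials; change
    values (window minus the same trial's baseline) feed the paired tests.
    """
    fs = sig.sampling_rate
    values = np.asarray(sig.values)
    n = values.size
    per_trial: dict[str, list[float]] = {k: [] for k in
                                         ("baseline", "transient", "sustained", "post")}
    for windows in _per_trial_windows(protocol, fs, n):
        for key, rng in windows.items():
            if rng is None:
                continue
            i0, i1 = rng
            per_trial[key].append(float(values[i0:i1].mean()))

    def agg(key):
        vals = per_trial[key]
        return float(np.mean(vals)) if vals else float("nan")

    base, tr, su, po = (agg(k) for k in ("baseline", "transient", "sustained", "post"))
    return WindowStats(baseline=base, transient=tr, sustained=su, post=po,
                       transient_change=tr - base, sustained_change=su - base,
                       post_change=po - base, per_trial=per_trial)


def trial_matrix(values: np.ndarray, protocol: StimProtocol,
                 sampling_rate: float) -> np.ndarray:
    """Reshape a concatenated-recording series to (n_trials, frames_per_trial)."""
    values = np.asarray(values)
    per = int(round(protocol.trial_duration * sampling_rate))
    n_full = min(protocol.n_trials, values.size // per)
    return values[:n_full * per].reshape(n_full, per)
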