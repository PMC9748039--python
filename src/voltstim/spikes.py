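"""Spike detection and spike signal-to-baseline ratio (SBR).

Detection follows the adaptive-threshold scheme used for somatic voltage
indicators: the trace is zero-phase high-pass filtered above 120 Hz, and
frames whose filtered value exceeds ``k_sd`` (default 4) baseline-noise
standard deviations are collapsed into spike peaks. Baseline noise is
estimated with a spike-insensitive clip procedure: the trace is smoothed
with a ±100-frame moving mean, values above the smoothed trace (candidate
spikes) are replaced by it, and the SD of the result is corrected for the
one-sided clipping so that a spike-free Gaussian input returns exactly its
own SD.

SBR is the neuron's mean spike amplitude divided by the SD of the
spike-removed trace; spike amplitude is the peak fluorescence minus the
lowest value within the three frames before the peak.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
from scipy import signal

from .containers import FluorescenceTrace, SbrReport, SpikeTrain

__all__ = [
    "highpass_trace",
    "estimate_baseline_fluctuation",
    "detect_spikes",
    "spike_amplitudes",
    "compute_sbr",
]

_SMOOTH_HALF_WINDOW = 100  # frames on each side of the moving mean


def highpass_trace(trace: FluorescenceTrace, cutoff: float = 120.0) -> FluorescenceTrace:
    """Zero-phase order-4 Butterworth high-pass (forward-backward)."""
    nyquist = trace.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(4, cutoff / nyquist, btype="highpass", output="sos")
    return trace.with_values(signal.sosfiltfilt(sos, trace.values))


def _moving_mean(values: np.ndarray, half_window: int) -> np.ndarray:
    """±half_window moving mean with a truncated (shrinking) window at edges."""
    n = values.size
    c = np.concatenate([[0.0], np.cumsum(values)])
    hi = np.minimum(np.arange(n) + half_window + 1, n)
    lo = np.maximum(np.arange(n) - half_window, 0)
    return (c[hi] - c[lo]) / (hi - lo)


# variance of min(z, 0) for standard normal z: one-sided clipping retains
# half the variance; used to undo the clipping bias below
_HALF_CLIP_VAR = 0.5


def estimate_baseline_fluctuation(trace: Union[FluorescenceTrace, np.ndarray],
                                  half_window: int = _SMOOTH_HALF_WINDOW,
                                  doubly_smoothed: bool = False) -> float:
    """Spike-insensitive estimate of the baseline fluctuation SD.

    The trace is smoothed with a ±``half_window`` moving mean; values above
    the smoothed trace are replaced by it, which removes positive-going
    spikes while leaving slow fluctuations intact. The default estimator
    combines the variance of the smoothed (slow) component with the
    fast-residual variance recovered from the surviving (below-baseline)
    half of the residuals:

    ``sd = sqrt( var(smoothed) + 2·mean( (clipped − smoothed)² ) )``

    so a spike-free Gaussian trace returns its own SD and a slow sinusoid
    returns close to its RMS. ``doubly_smoothed=True`` instead returns the
    SD of the re-smoothed clipped trace (the slow-fluctuation reading).
    """
    values = trace.values if isinstance(trace, FluorescenceTrace) else np.asarray(trace, float)
    if values.size <= 2 * half_window + 1:
        warnings.warn("trace shorter than the smoothing window; window shrinks")
    smoothed = _moving_mean(values, half_window)
    clipped = np.minimum(values, smoothed)
    if doubly_smoothed:
        return float(_moving_mean(clipped, half_window).std())
    resid = clipped - smoothed
    return float(np.sqrt(smoothed.var() + np.mean(resid ** 2) / _HALF_CLIP_VAR))


def _collapse_runs_to_peaks(above: np.ndarray, series: np.ndarray) -> np.ndarray:
    """Reduce each contiguous supra-threshold run to its local-maximum frame."""
    if not above.any():
        return np.empty(0, dtype=int)
    idx = np.flatnonzero(above)
    run_starts = np.flatnonzero(np.diff(idx) > 1)
    bounds = np.split(idx, run_starts + 1)
    return np.array([run[np.argmax(series[run])] for run in bounds], dtype=int)


def _merge_close_peaks(peaks: np.ndarray, series: np.ndarray,
                       min_separation: int) -> np.ndarray:
    """Merge peaks closer than ``min_separation`` frames, keeping the larger."""
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < min_separation:
            if series[p] > series[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return np.asarray(kept, dtype=int)


def detect_spikes(trace: FluorescenceTrace, k_sd: float = 4.0,
                  cutoff: float = 120.0,
                  baseline_sd: Optional[float] = None,
                  min_separation: int = 2,
                  absolute_threshold: Optional[float] = None) -> SpikeTrain:
    """Detect spikes as >``k_sd``-SD deflections of the high-passed trace.

    ``baseline_sd`` defaults to the clip-based baseline fluctuation of the
    high-passed trace itself, so the threshold adapts to the recording's fast
    noise while ignoring the spikes. Contiguous supra-threshold runs collapse
    to their local maximum; peaks closer than ``min_separation`` frames merge
    keeping the larger. Amplitudes are measured on the input trace (expected
    to be the detrended, not high-passed, fluorescence).
    """
    hp = highpass_trace(trace, cutoff).values
    if baseline_sd is None:
        baseline_sd = estimate_baseline_fluctuation(hp)
    if baseline_sd <= 0:
        if absolute_threshold is None:
            absolute_threshold = 0.5 * hp.max() if hp.max() > 0 else np.inf
        warnings.warn("baseline SD is zero (noiseless trace); falling back to "
                      f"absolute threshold {absolute_threshold:.4g}")
        threshold = absolute_threshold
    else:
        threshold = k_sd * baseline_sd
    peaks = _collapse_runs_to_peaks(hp > threshold, hp)
    peaks = _merge_close_peaks(peaks, hp, min_separation)
    amps = spike_amplitudes(trace, peaks)
    return SpikeTrain(spike_frames=peaks, spike_amplitudes=amps,
                      threshold_used=float(threshold), baseline_sd=float(baseline_sd))


def spike_amplitudes(trace: FluorescenceTrace,
                     spike_frames: np.ndarray) -> np.ndarray:
    """Peak fluorescence minus the minimum of the 3 frames before the peak."""
    values = trace.values
    out = np.empty(len(spike_frames))
    for i, pk in enumerate(np.asarray(spike_frames, dtype=int)):
        lo = pk - 3
        if lo < 0:
            warnings.warn(f"spike at frame {pk} has fewer than 3 preceding frames")
            lo = 0
        window = values[lo:pk]
        base = window.min() if window.size else values[pk]
        out[i] = values[pk] - base
    return out


def compute_sbr(trace: FluorescenceTrace, spikes: SpikeTrain) -> Optional[SbrReport]:
    """Mean spike amplitude over the SD of the spike-removed trace.

    Returns ``None`` (with a warning) when the train is empty: without
    spikes the amplitude unit is undefined.
    """
    from .vm import remove_spikes  # local import to keep module layering acyclic

    if spikes.n_spikes == 0:
        warnings.warn("SBR undefined: no spikes detected")
        return None
    removed = remove_spikes(trace, spikes)
    noise = float(removed.values.std())
    mean_amp = spikes.mean_amplitude()
    return SbrReport(mean_spike_amplitude=mean_amp,
                     subthreshold_baseline_noise=noise,
                     sbr=mean_amp / noise if noise > 0 else float("inf"),
                     n_spikes=spikes.n_spikes)
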