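"""Display helpers. Smoothing here is cosmetic and never feeds statistics."""

from __future__ import annotations

import numpy as np

__all__ = ["display_smooth", "plot_trace_with_spikes", "plot_pulse_average",
           "plot_plv_spectrum"]


def display_smooth(values: np.ndarray, sampling_rate: float,
                   window_s: float) -> np.ndarray:
    """Rectangular smoothing for plots (e.g. 30 ms Vm, 300 ms firing rate)."""
    width = max(1, int(round(window_s * sampling_rate)))
    kernel = np.ones(width) / width
    return np.convolve(np.asarray(values, float), kernel, mode="same")


def plot_trace_with_spikes(ax, trace, spikes=None, protocol=None):
    t = trace.times()
    ax.plot(t, trace.values, color="k", lw=0.5)
    if spikes is not None and spikes.n_spikes:
        ax.plot(spikes.spike_frames / trace.sampling_rate,
                np.full(spikes.n_spikes, trace.values.max() * 1.02), "|",
                color="r", ms=6)
    if protocol is not None:
        for t0 in protocol.trial_starts():
            ax.axvspan(t0 + protocol.dbs_window[0], t0 + protocol.dbs_window[1],
                       color="goldenrod", alpha=0.2, lw=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fluorescence (a.u.)")
    return ax


def plot_pulse_average(ax, avg, smooth_s: float | None = None,
                       sampling_rate: float = 828.0, **kwargs):
    mean = avg.mean
    if smooth_s:
        mean = display_smooth(mean, sampling_rate, smooth_s)
    line, = ax.plot(avg.lags * 1e3, mean, **kwargs)
    ax.fill_between(avg.lags * 1e3, mean - avg.sem, mean + avg.sem,
                    alpha=0.3, color=line.get_color(), lw=0)
    ax.axvline(0.0, color="goldenrod", lw=1)
    ax.set_xlabel("lag from pulse onset (ms)")
    return ax


def plot_plv_spectrum(ax, frequencies, plvs, **kwargs):
    ax.plot(frequencies, plvs, **kwargs)
    ax.set_xscale("log")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("spike-Vm PLV")
    ax.set_ylim(0, 1)
    return ax
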