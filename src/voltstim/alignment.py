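"""Event-triggered averaging of Vm and firing rate.

Pulse-triggered averages are built at native frame resolution (~1.21 ms at
828 Hz): a snippet per event, the per-neuron mean across events, a pre-onset
normalization-window subtraction, then the across-neuron mean and SEM.
Events whose lag window crosses a trial boundary are dropped (counted, not
padded). Default normalization windows follow the study conventions: 10 ms
before DBS pulses at 40 Hz, 5 ms at 140 Hz, 50 ms before optogenetic
pulses. Display smoothing lives in the plotting utilities, never here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .containers import StimProtocol, VmTrace
from .spectral import morlet_power

__all__ = [
    "PulseAlignedAverage",
    "RegressionFit",
    "event_triggered_average",
    "population_average",
    "evoked_change",
    "onset_response_timing",
    "opto_entrainment_power",
    "depolarization_vs_suppression",
    "default_norm_window",
]


@dataclass
class PulseAlignedAverage:
    lags: np.ndarray          # seconds relative to event onset
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    norm_window: float        # seconds before onset used for re-referencing
    n_dropped: int = 0


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def default_norm_window(dbs_frequency: Optional[float] = None,
                        opto: bool = False) -> float:
    """Pre-onset normalization span: 10/5 ms for 40/140 Hz pulses, 50 ms opto."""
    if opto:
        return 0.050
    if dbs_frequency is None:
        return 0.010
    return 0.005 if dbs_frequency >= 100 else 0.010


def event_triggered_average(values: np.ndarray, sampling_rate: float,
                            event_times: np.ndarray,
                            lag_range: tuple[float, float],
                            norm_window: float = 0.010,
                            trial_edges: Optional[np.ndarray] = None) -> PulseAlignedAverage:
    """Average snippets of one neuron's signal around event onsets.

    ``event_times`` are absolute seconds in the concatenated recording.
    The mean over the ``norm_window`` seconds before onset is subtracted
    from the event-averaged snippet.
    """
    if norm_window <= 0:
        raise ValueError("norm_window must be positive")
    values = np.asarray(values, dtype=float)
    n = values.size
    lag_lo = int(np.floor(lag_range[0] * sampling_rate))
    lag_hi = int(np.ceil(lag_range[1] * sampling_rate))
    lags_f = np.arange(lag_lo, lag_hi + 1)
    need_pre = max(-lag_lo, int(np.ceil(norm_window * sampling_rate)))
    edges = np.sort(np.asarray(trial_edges, dtype=int)) if trial_edges is not None else None

    snippets, dropped = [], 0
    for t in np.asarray(event_times, dtype=float):
        f0 = int(round(t * sampling_rate))
        a, b = f0 - need_pre, f0 + lag_hi + 1
        if a < 0 or b > n:
            dropped += 1
            continue
        if edges is not None and np.searchsorted(edges, a, "right") != np.searchsorted(edges, b - 1, "right"):
            dropped += 1
            continue
        snippets.append(values[f0 + lag_lo:f0 + lag_hi + 1])
    if not snippets:
        raise ValueError("no events with a full lag window inside the recording")
    if dropped:
        warnings.warn(f"{dropped} events dropped (lag window crosses an edge)")
    snip = np.asarray(snippets)
    mean = snip.mean(axis=0)
    sem = snip.std(axis=0, ddof=1) / np.sqrt(snip.shape[0]) if snip.shape[0] > 1 else np.zeros_like(mean)
    # subtract the pre-onset normalization-window mean of the averaged snippet
    nw = int(round(norm_window * sampling_rate))
    pre_mask = (lags_f >= -nw) & (lags_f < 0)
    if pre_mask.any():
        mean = mean - mean[pre_mask].mean()
    return PulseAlignedAverage(lags=lags_f / sampling_rate, mean=mean, sem=sem,
                               n_events=snip.shape[0], norm_window=norm_window,
                               n_dropped=dropped)


def population_average(averages: Sequence[PulseAlignedAverage]) -> PulseAlignedAverage:
    """Across-neuron mean and SEM of per-neuron pulse-aligned averages."""
    if not averages:
        raise ValueError("need at least one per-neuron average")
    stack = np.asarray([a.mean for a in averages])
    mean = stack.mean(axis=0)
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
           if stack.shape[0] > 1 else np.zeros_like(mean))
    return PulseAlignedAverage(lags=averages[0].lags, mean=mean, sem=sem,
                               n_events=sum(a.n_events for a in averages),
                               norm_window=averages[0].norm_window)


def evoked_change(avg: PulseAlignedAverage,
                  lag_range: Optional[tuple[float, float]] = None) -> float:
    """Max minus min of the pulse-averaged signal within the inter-pulse lags."""
    sel = np.ones_like(avg.lags, dtype=bool)
    if lag_range is not None:
        sel = (avg.lags >= lag_range[0]) & (avg.lags <= lag_range[1])
    seg = avg.mean[sel]
    return float(seg.max() - seg.min())


def onset_response_timing(trial_signals: np.ndarray, lags: np.ndarray,
                          baseline_mask: np.ndarray,
                          alpha: float = 0.05,
                          n_sd: float = 2.0) -> dict:
    """Locate the first significant post-onset deviation and the peak lag.

    Two detectors are reported: (a) per-lag paired comparison of each
    replicate's value against its own baseline-window mean (two-sided
    t-test at ``alpha``, uncorrected, mirroring per-time-point testing);
    (b) the first lag where the mean trace exceeds ``n_sd`` standard
    deviations of its own baseline-lag distribution. Peak lag is the argmax
    of the mean trace after onset.
    """
    trial_signals = np.atleast_2d(np.asarray(trial_signals, dtype=float))
    lags = np.asarray(lags, dtype=float)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    post = lags > 0
    mean_trace = trial_signals.mean(axis=0)

    base_per_rep = trial_signals[:, baseline_mask].mean(axis=1)
    first_ttest = None
    if trial_signals.shape[0] >= 2:
        for j in np.flatnonzero(post):
            diff = trial_signals[:, j] - base_per_rep
            if np.allclose(diff.std(), 0):
                significant = bool(abs(diff.mean()) > 0)
            else:
                significant = stats.ttest_1samp(diff, 0.0).pvalue < alpha
            if significant and mean_trace[j] > base_per_rep.mean():
                first_ttest = float(lags[j])
                break

    base_mean = mean_trace[baseline_mask].mean()
    base_sd = mean_trace[baseline_mask].std()
    crossings = np.flatnonzero(post & (mean_trace > base_mean + n_sd * base_sd))
    first_sd = float(lags[crossings[0]]) if crossings.size else None

    post_idx = np.flatnonzero(post)
    peak = float(lags[post_idx[np.argmax(mean_trace[post_idx])]]) if post_idx.size else None
    return {"first_significant_ttest": first_ttest,
            "first_crossing_sd": first_sd,
            "peak_lag": peak}


def opto_entrainment_power(vm: VmTrace, protocol: StimProtocol,
                           opto_frequency: float = 8.0,
                           cycles: float = 5.0) -> dict:
    """Optogenetic-band Vm power in the baseline, stimulation and post windows.

    Power is the Morlet power at ``opto_frequency`` averaged per window per
    trial, then across trials; change values are Stim − Base and Post − Base.
    """
    fs = vm.sampling_rate
    min_win = cycles / opto_frequency
    if (protocol.dbs_window[1] - protocol.dbs_window[0]) < 0.5:
        raise ValueError("windows must span at least 0.5 s")
    if (protocol.dbs_window[1] - protocol.dbs_window[0]) < min_win:
        warnings.warn(f"window shorter than {cycles:g} cycles at "
                      f"{opto_frequency:g} Hz; estimate is edge-dominated")
    dec = morlet_power(vm, np.array([opto_frequency]), cycles=cycles)
    power = dec.power[0]
    base_vals, stim_vals, post_vals = [], [], []
    n = power.size
    for t0 in protocol.trial_starts():
        onset = int(round((t0 + protocol.dbs_window[0]) * fs))
        offset = int(round((t0 + protocol.dbs_window[1]) * fs))
        trial_end = int(round((t0 + protocol.trial_duration) * fs))
        b0 = max(int(round(t0 * fs)), onset - int(round(fs)))
        p1 = min(offset + int(round(fs)), trial_end, n)
        if onset > b0:
            base_vals.append(power[b0:onset].mean())
        if offset > onset and offset <= n:
            stim_vals.append(power[onset:offset].mean())
        if p1 > offset:
            post_vals.append(power[offset:p1].mean())
    base, stim, post = (float(np.mean(v)) if v else float("nan")
                        for v in (base_vals, stim_vals, post_vals))
    return {"baseline": base, "stim": stim, "post": post,
            "stim_change": stim - base, "post_change": post - base,
            "stim_ratio": stim / base if base > 0 else float("nan")}


def depolarization_vs_suppression(vm_change: np.ndarray,
                                  suppression: np.ndarray) -> Optional[RegressionFit]:
    """OLS regression of entrainment suppression on Vm depolarization.

    ``vm_change`` must already be in spike-amplitude units (the per-neuron
    Vm normalization); ``suppression`` is the per-neuron change in
    optogenetic-band power or PLV (DBS − baseline).
    """
    x = np.asarray(vm_change, dtype=float)
    y = np.asarray(suppression, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        warnings.warn("regression needs at least 3 neurons")
        return None
    if np.allclose(x.var(), 0):
        warnings.warn("degenerate regressor (zero variance)")
        return None
    fit = stats.linregress(x, y)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2),
                         p_value=float(fit.pvalue), n=int(x.size))
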