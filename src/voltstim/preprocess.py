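"""Photobleach detrending with the stimulation window excluded.

Electrical stimulation produces large subthreshold deflections that would
bias a bleaching fit, so before fitting the trend each DBS window is
replaced by the mean of the 10 frames immediately before onset and the 10
frames immediately after offset. The straight line fitted to that
interpolated trace is then subtracted from the *original* trace, making the
slope sensitive only to the pre- and post-stimulation fluorescence.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import FluorescenceTrace, StimProtocol

__all__ = ["interpolate_stim_window", "detrend_trace"]

_N_FLANK = 10  # frames averaged on each side of the stimulation window


def _trial_bounds(protocol: StimProtocol, fs: float, n: int):
    starts = protocol.trial_boundaries(fs)
    stops = np.append(starts[1:], n)
    return starts, stops


def interpolate_stim_window(trace: FluorescenceTrace,
                            protocol: StimProtocol) -> FluorescenceTrace:
    """Replace each DBS window with the mean of its 10-frame flanks.

    The replacement is the constant mean of the 10 frames immediately before
    stimulation onset and the 10 frames immediately after offset (20 frames
    total), truncated with a warning where a window abuts a trial edge.
    """
    fs = trace.sampling_rate
    values = trace.values.copy()
    n = values.size
    t_starts, t_stops = _trial_bounds(protocol, fs, n)
    for (a, b), t0, t1 in zip(protocol.dbs_window_frames(fs), t_starts, t_stops):
        a, b = max(a, 0), min(b, n)
        if a >= b:
            continue
        pre = values[max(a - _N_FLANK, t0):a]
        post = values[b:min(b + _N_FLANK, t1)]
        if pre.size < _N_FLANK or post.size < _N_FLANK:
            warnings.warn("stimulation window abuts a trial edge; flank "
                          f"shrunk to {pre.size}+{post.size} frames")
        flank = np.concatenate([pre, post])
        if flank.size == 0:
            continue
        values[a:b] = flank.mean()
    return trace.with_values(values)


def detrend_trace(trace: FluorescenceTrace, protocol: StimProtocol) -> FluorescenceTrace:
    """Remove a least-squares straight line fitted outside the DBS windows.

    The line is fitted to the stimulation-window-interpolated trace and
    subtracted from the original, so stimulation-evoked depolarization
    survives in the residual while bleaching and offset are removed. A
    degenerate (constant) trace returns zeros.
    """
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames to fit a trend")
    interp = interpolate_stim_window(trace, protocol)
    t = np.arange(trace.n_frames, dtype=float)
    if np.ptp(interp.values) == 0:
        fitted = np.full_like(t, interp.values[0])
    else:
        slope, intercept = np.polyfit(t, interp.values, 1)
        fitted = slope * t + intercept
    return trace.with_values(trace.values - fitted)
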