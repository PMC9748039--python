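"""Shared in-memory containers for the voltage-imaging analysis pipeline.

All traces are sampled on a single frame grid (one value per camera frame).
Recordings are trial-structured: multi-second trials concatenated end to end,
with ``trial_boundaries`` giving the first frame of each trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "StimProtocol",
    "FluorescenceTrace",
    "SpikeTrain",
    "SbrReport",
    "VmTrace",
    "RateTrace",
    "WindowStats",
    "PlvResult",
    "VoltageMovie",
    "RoiMask",
    "ShiftSeries",
]


@dataclass
class StimProtocol:
    """Stimulation protocol for one recording.

    All times are seconds relative to the start of each trial; every trial
    shares the same within-trial layout.

    Parameters
    ----------
    n_trials : number of concatenated trials.
    trial_duration : trial length in seconds.
    dbs_window : half-open ``[start, end)`` of the electrical stimulation
        period within each trial, in seconds.
    dbs_frequency : pulse rate of the stimulation train, Hz.
    dbs_pulse_times : pulse onset times within a trial, seconds.
    dbs_amplitude_ua : annotation only; the analysis never uses it.
    opto_onsets : optogenetic light-pulse onsets within a trial (seconds),
        empty when no optogenetic stimulation was delivered.
    opto_pulse_width : light pulse duration, seconds.
    opto_frequency : light pulse rate, Hz (annotation).
    """

    n_trials: int
    trial_duration: float
    dbs_window: tuple[float, float]
    dbs_frequency: float
    dbs_pulse_times: np.ndarray
    dbs_amplitude_ua: Optional[float] = None
    opto_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    opto_pulse_width: float = 0.042
    opto_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        self.dbs_pulse_times = np.asarray(self.dbs_pulse_times, dtype=float)
        self.opto_onsets = np.asarray(self.opto_onsets, dtype=float)
        lo, hi = self.dbs_window
        if self.dbs_pulse_times.size and (
            self.dbs_pulse_times.min() < lo or self.dbs_pulse_times.max() >= hi
        ):
            raise ValueError("DBS pulse times must lie inside dbs_window")
        if hi > self.trial_duration or lo < 0:
            raise ValueError("dbs_window must lie inside the trial")

    # -- absolute (concatenated-recording) views ---------------------------
    def trial_starts(self) -> np.ndarray:
        return np.arange(self.n_trials) * self.trial_duration

    def absolute_dbs_pulse_times(self) -> np.ndarray:
        """DBS pulse onsets over the whole concatenated recording, seconds."""
        return (self.trial_starts()[:, None] + self.dbs_pulse_times[None, :]).ravel()

    def absolute_opto_onsets(self) -> np.ndarray:
        if self.opto_onsets.size == 0:
            return np.empty(0)
        return (self.trial_starts()[:, None] + self.opto_onsets[None, :]).ravel()

    def dbs_window_frames(self, sampling_rate: float) -> list[tuple[int, int]]:
        """Per-trial ``[start, stop)`` frame ranges of the DBS window."""
        out = []
        for t0 in self.trial_starts():
            a = int(round((t0 + self.dbs_window[0]) * sampling_rate))
            b = int(round((t0 + self.dbs_window[1]) * sampling_rate))
            out.append((a, b))
        return out

    def trial_boundaries(self, sampling_rate: float) -> np.ndarray:
        return np.round(self.trial_starts() * sampling_rate).astype(int)

    def n_frames(self, sampling_rate: float) -> int:
        return int(round(self.n_trials * self.trial_duration * sampling_rate))

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "trial_duration": self.trial_duration,
            "dbs_window": list(self.dbs_window),
            "dbs_frequency": self.dbs_frequency,
            "dbs_pulse_times": self.dbs_pulse_times.tolist(),
            "dbs_amplitude_ua": self.dbs_amplitude_ua,
            "opto_onsets": self.opto_onsets.tolist(),
            "opto_pulse_width": self.opto_pulse_width,
            "opto_frequency": self.opto_frequency,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimProtocol":
        d = dict(d)
        d["dbs_window"] = tuple(d["dbs_window"])
        d["dbs_pulse_times"] = np.asarray(d["dbs_pulse_times"], dtype=float)
        d["opto_onsets"] = np.asarray(d.get("opto_onsets", []), dtype=float)
        return cls(**d)


@dataclass
class FluorescenceTrace:
    """One neuron's fluorescence versus frame index."""

    values: np.ndarray
    sampling_rate: float
    trial_boundaries: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=int))
    protocol: Optional[StimProtocol] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trial_boundaries = np.asarray(self.trial_boundaries, dtype=int)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.size

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    def with_values(self, values: np.ndarray) -> "FluorescenceTrace":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SpikeTrain:
    """Detected spikes for one neuron."""

    spike_frames: np.ndarray
    spike_amplitudes: np.ndarray
    threshold_used: float
    baseline_sd: float

    def __post_init__(self) -> None:
        self.spike_frames = np.asarray(self.spike_frames, dtype=int)
        self.spike_amplitudes = np.asarray(self.spike_amplitudes, dtype=float)
        if self.spike_frames.size > 1 and np.any(np.diff(self.spike_frames) <= 0):
            raise ValueError("spike frames must be strictly increasing")
        if self.spike_frames.size != self.spike_amplitudes.size:
            raise ValueError("one amplitude per spike required")

    @property
    def n_spikes(self) -> int:
        return self.spike_frames.size

    def mean_amplitude(self) -> float:
        return float(np.mean(self.spike_amplitudes)) if self.n_spikes else float("nan")


@dataclass
class SbrReport:
    """Spike signal-to-baseline ratio for one neuron."""

    mean_spike_amplitude: float
    subthreshold_baseline_noise: float
    sbr: float
    n_spikes: int


@dataclass
class VmTrace:
    """Subthreshold membrane-voltage proxy in spike-amplitude units."""

    values: np.ndarray
    sampling_rate: float
    trial_boundaries: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=int))
    normalization: str = "none"  # none | baseline_subtracted
    protocol: Optional[StimProtocol] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trial_boundaries = np.asarray(self.trial_boundaries, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.values.size

    def with_values(self, values, normalization=None) -> "VmTrace":
        out = replace(self, values=np.asarray(values, dtype=float))
        if normalization is not None:
            out.normalization = normalization
        return out


@dataclass
class RateTrace:
    """Instantaneous firing-rate estimate, spikes/s per frame."""

    values: np.ndarray
    sampling_rate: float
    smoothing_window: float
    trial_boundaries: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class WindowStats:
    """Trial-averaged means of a signal in the quantification windows.

    ``transient`` covers 0-0.15 s from DBS onset, ``sustained`` 0.15-1 s,
    ``baseline`` the 1 s immediately before onset and ``post`` a matched
    window after offset. Change values are window minus baseline.
    """

    baseline: float
    transient: float
    sustained: float
    post: float
    transient_change: float
    sustained_change: float
    post_change: float
    per_trial: Optional[dict] = None


@dataclass
class PlvResult:
    """Phase-locking value with resampling-based uncertainty."""

    plv: float
    n: int
    frequency: Optional[float] = None
    bootstrap_sd: Optional[float] = None
    null_distribution: Optional[np.ndarray] = None
    p_value: Optional[float] = None


@dataclass
class VoltageMovie:
    """A (time, y, x) fluorescence image stack."""

    frames: np.ndarray
    sampling_rate: float
    trial_boundaries: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=int))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("movie must be (time, y, x)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class RoiMask:
    """Binary region-of-interest mask for one neuron."""

    mask: np.ndarray
    label: str = "neuron"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() < 1:
            raise ValueError("mask must contain at least one pixel")


@dataclass
class ShiftSeries:
    """Per-frame rigid displacements (dy, dx) in pixels.

    Convention: ``shifts[i]`` is the displacement of frame ``i`` relative to
    the reference, row/column order, origin top-left. Correcting a frame
    means translating it by ``-shifts[i]``.
    """

    shifts: np.ndarray
    reference: str = "mean"

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n_frames, 2)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")

    def __len__(self) -> int:
        return self.shifts.shape[0]
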