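"""Time-frequency power, band phase, and spike-Vm phase locking.

Power uses a 5-cycle complex Morlet transform (unit-energy wavelets). Band
phase uses a zero-phase order-2 Butterworth band-pass (±2 Hz around each
center, centers on a 2 Hz grid) followed by the analytic-signal (Hilbert)
phase, with the cosine convention: phase 0 at the band-passed signal peak.

The phase-locking value of a spike set is the modulus of the mean resultant
vector of the unit phase vectors at spike times,

    PLV(f) = | (1/N) Σ_n exp(i φ(f, n)) |,

in [0, 1]. Uncertainty comes from bootstrap resampling of spikes; inference
comes from a permutation null that redraws spike times uniformly within the
analysis window and re-reads phases from the same phase series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import PlvResult, SpikeTrain, VmTrace

__all__ = [
    "SpectralDecomposition",
    "SpikePhaseSet",
    "morlet_power",
    "stim_band_power_change",
    "bandpass_phase",
    "spike_phases",
    "plv",
    "bootstrap_plv",
    "permutation_test_plv",
    "band_averaged_plv",
    "plv_spectrum",
    "default_frequency_grid",
]

MIN_SPIKES_SINGLE_NEURON = 5  # single-neuron PLV reported only for N > 5


@dataclass
class SpectralDecomposition:
    frequencies: np.ndarray           # Hz
    coefficients: np.ndarray          # complex, (n_freq, n_frames)
    method: str = "morlet(5)"
    sampling_rate: float = 828.0

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2


@dataclass
class SpikePhaseSet:
    """Phases (radians) read at spike times for one frequency or band."""

    phases: np.ndarray
    frequency: float | None = None
    source: str = "single_neuron"     # single_neuron | population
    neuron_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.size and not np.all(np.isfinite(self.phases)):
            raise ValueError("phases must be finite")

    @property
    def n(self) -> int:
        return self.phases.size


def _morlet_wavelet(frequency: float, fs: float, cycles: float) -> np.ndarray:
    sigma_t = cycles / (2 * np.pi * frequency)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * frequency * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    w -= w.mean()                      # zero-mean: no DC leakage
    return w / np.sqrt(np.sum(np.abs(w) ** 2) / fs)  # unit energy per scale


def morlet_power(vm: VmTrace, frequencies: np.ndarray,
                 cycles: float = 5.0) -> SpectralDecomposition:
    """Complex Morlet transform with a fixed cycle count per frequency.

    Frequencies whose ``cycles``-cycle wavelet does not fit in the trace are
    dropped with a warning (the estimate would be all edge effect).
    """
    fs = vm.sampling_rate
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(frequencies >= fs / 2):
        raise ValueError("frequencies must be below Nyquist")
    n = vm.n_frames
    keep = []
    for f in frequencies:
        if cycles / f > n / fs:
            warnings.warn(f"{f} Hz dropped: fewer than {cycles} cycles fit the trace")
        else:
            keep.append(f)
    keep = np.asarray(keep)
    coeffs = np.empty((keep.size, n), dtype=complex)
    x = vm.values - vm.values.mean()
    for i, f in enumerate(keep):
        w = _morlet_wavelet(f, fs, cycles)
        coeffs[i] = sps.fftconvolve(x, np.conj(w[::-1]), mode="same")
    return SpectralDecomposition(frequencies=keep, coefficients=coeffs,
                                 method=f"morlet({cycles:g})", sampling_rate=fs)


def stim_band_power_change(vm: VmTrace, protocol, frequency: float,
                           cycles: float = 5.0) -> dict:
    """Stimulation-window band power relative to the 1 s pre-onset baseline.

    Returns per-trial mean power in the stimulation and baseline windows and
    the across-trial ratio and difference (ratio is the headline number).
    """
    dec = morlet_power(vm, np.array([frequency]), cycles=cycles)
    if dec.frequencies.size == 0:
        return {"ratio": float("nan"), "difference": float("nan"),
                "stim": [], "baseline": []}
    power = dec.power[0]
    fs = vm.sampling_rate
    stim_vals, base_vals = [], []
    for t0 in protocol.trial_starts():
        onset = int(round((t0 + protocol.dbs_window[0]) * fs))
        offset = int(round((t0 + protocol.dbs_window[1]) * fs))
        base0 = max(int(round(t0 * fs)), onset - int(round(fs)))
        if onset > base0:
            base_vals.append(power[base0:onset].mean())
        if offset > onset:
            stim_vals.append(power[onset:min(offset, power.size)].mean())
    stim_m, base_m = np.mean(stim_vals), np.mean(base_vals)
    return {"ratio": float(stim_m / base_m) if base_m > 0 else float("nan"),
            "difference": float(stim_m - base_m),
            "stim": stim_vals, "baseline": base_vals}


def bandpass_phase(vm: VmTrace, center: float, half_bandwidth: float = 2.0,
                   order: int = 2) -> np.ndarray:
    """Zero-phase band-pass then analytic-signal phase, radians in (-π, π]."""
    fs = vm.sampling_rate
    lo, hi = center - half_bandwidth, center + half_bandwidth
    if lo <= 0 or hi >= fs / 2:
        raise ValueError(f"band [{lo}, {hi}] Hz outside (0, Nyquist)")
    sos = sps.butter(order, [lo / (fs / 2), hi / (fs / 2)],
                     btype="bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, vm.values - vm.values.mean())
    return np.angle(sps.hilbert(filtered))


def spike_phases(phase_series: np.ndarray, spikes: SpikeTrain | np.ndarray,
                 window: tuple[int, int] | None = None,
                 frequency: float | None = None,
                 neuron_id: int = 0) -> SpikePhaseSet:
    """Read the phase series at spike frames, optionally within a frame window."""
    frames = spikes.spike_frames if isinstance(spikes, SpikeTrain) else np.asarray(spikes, int)
    if window is not None:
        lo, hi = window
        frames = frames[(frames >= lo) & (frames < hi)]
    frames = frames[(frames >= 0) & (frames < len(phase_series))]
    return SpikePhaseSet(phases=np.asarray(phase_series)[frames], frequency=frequency,
                         neuron_ids=np.full(frames.size, neuron_id, dtype=int))


def concatenate_phase_sets(sets: list[SpikePhaseSet]) -> SpikePhaseSet:
    """Pool spikes across neurons (population PLV) keeping per-neuron provenance."""
    phases = np.concatenate([s.phases for s in sets]) if sets else np.empty(0)
    ids = np.concatenate([s.neuron_ids for s in sets]) if sets else np.empty(0, dtype=int)
    freq = sets[0].frequency if sets else None
    return SpikePhaseSet(phases=phases, frequency=freq, source="population",
                         neuron_ids=ids)


def plv(phases: SpikePhaseSet | np.ndarray,
        enforce_min_spikes: bool = False) -> PlvResult | None:
    """Modulus of the mean resultant vector of the spike phases."""
    p = phases.phases if isinstance(phases, SpikePhaseSet) else np.asarray(phases, float)
    freq = phases.frequency if isinstance(phases, SpikePhaseSet) else None
    if p.size == 0:
        warnings.warn("PLV undefined for an empty phase set")
        return None
    if enforce_min_spikes and p.size <= MIN_SPIKES_SINGLE_NEURON:
        warnings.warn(f"PLV suppressed: {p.size} spikes ≤ {MIN_SPIKES_SINGLE_NEURON}")
        return None
    value = float(np.abs(np.mean(np.exp(1j * p))))
    return PlvResult(plv=value, n=int(p.size), frequency=freq)


def bootstrap_plv(phases: SpikePhaseSet | np.ndarray, replicates: int = 1000,
                  seed: int = 0) -> float:
    """SD of the PLV over with-replacement resamples of the spike set."""
    p = phases.phases if isinstance(phases, SpikePhaseSet) else np.asarray(phases, float)
    if p.size < 2:
        raise ValueError("bootstrap needs at least 2 spikes")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, p.size, size=(replicates, p.size))
    vec = np.exp(1j * p)[idx]
    return float(np.abs(vec.mean(axis=1)).std())


def permutation_test_plv(phase_series: np.ndarray,
                         spikes: SpikeTrain | np.ndarray,
                         window: tuple[int, int],
                         replicates: int = 1000,
                         seed: int = 0,
                         frequency: float | None = None,
                         scheme: str = "uniform") -> PlvResult | None:
    """Permutation test of spike-phase locking against resampled spike times.

    The null redraws the same number of spike frames uniformly within the
    analysis window (``scheme="uniform"``) or circularly time-shifts the
    observed train (``scheme="shift"``) and re-reads phases from the same
    series; p = (1 + #{null ≥ observed}) / (1 + replicates).
    """
    lo, hi = window
    if frequency is not None and (hi - lo) < phase_sampling_guard(frequency):
        warnings.warn("window shorter than one cycle of the target frequency")
        return None
    obs_set = spike_phases(phase_series, spikes, window=window, frequency=frequency)
    n = obs_set.n
    if n <= MIN_SPIKES_SINGLE_NEURON:
        warnings.warn(f"permutation test needs > {MIN_SPIKES_SINGLE_NEURON} spikes, got {n}")
        return None
    observed = float(np.abs(np.mean(np.exp(1j * obs_set.phases))))
    rng = np.random.default_rng(seed)
    series = np.asarray(phase_series)
    if scheme == "uniform":
        frames = rng.integers(lo, hi, size=(replicates, n))
        null = np.abs(np.exp(1j * series[frames]).mean(axis=1))
    elif scheme == "shift":
        orig = (spikes.spike_frames if isinstance(spikes, SpikeTrain)
                else np.asarray(spikes, int))
        orig = orig[(orig >= lo) & (orig < hi)]
        shifts = rng.integers(1, hi - lo, size=replicates)
        rolled = (orig[None, :] - lo + shifts[:, None]) % (hi - lo) + lo
        null = np.abs(np.exp(1j * series[rolled]).mean(axis=1))
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    p = (1.0 + np.sum(null >= observed)) / (1.0 + replicates)
    return PlvResult(plv=observed, n=n, frequency=frequency,
                     null_distribution=null, p_value=float(p))


def phase_sampling_guard(frequency: float, sampling_rate: float = 828.0) -> int:
    """Frames spanning one cycle of ``frequency`` (permutation-window floor)."""
    return int(np.ceil(sampling_rate / frequency))


def band_averaged_plv(frequencies: np.ndarray, plvs: np.ndarray,
                      band: tuple[float, float] = (3.0, 12.0)) -> float:
    """Unweighted mean PLV over the grid centers inside ``band`` (inclusive)."""
    frequencies = np.asarray(frequencies, dtype=float)
    plvs = np.asarray(plvs, dtype=float)
    sel = (frequencies >= band[0]) & (frequencies <= band[1])
    if not sel.any():
        raise ValueError(f"no grid frequencies inside band {band}")
    return float(plvs[sel].mean())


def default_frequency_grid(sampling_rate: float = 828.0,
                           f_max: float = 200.0, step: float = 2.0,
                           half_bandwidth: float = 2.0) -> np.ndarray:
    """2 Hz-step filter-bank centers with valid band edges."""
    grid = np.arange(step, f_max + step / 2, step)
    return grid[(grid - half_bandwidth > 0)
                & (grid + half_bandwidth < sampling_rate / 2)]


def plv_spectrum(vm: VmTrace, spikes: SpikeTrain | np.ndarray,
                 window: tuple[int, int],
                 frequencies: np.ndarray | None = None,
                 half_bandwidth: float = 2.0, order: int = 2) -> tuple[np.ndarray, np.ndarray, int]:
    """Spike-Vm PLV across the band-pass filter bank.

    Returns ``(frequencies, plv, n_spikes)`` with one PLV per grid center;
    spikes outside ``window`` are excluded.
    """
    if frequencies is None:
        frequencies = default_frequency_grid(vm.sampling_rate)
    out = np.full(len(frequencies), np.nan)
    n_used = 0
    for i, f in enumerate(frequencies):
        phase = bandpass_phase(vm, f, half_bandwidth=half_bandwidth, order=order)
        ps = spike_phases(phase, spikes, window=window, frequency=f)
        n_used = ps.n
        if ps.n:
            out[i] = np.abs(np.mean(np.exp(1j * ps.phases)))
    return np.asarray(frequencies, float), out, n_used
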