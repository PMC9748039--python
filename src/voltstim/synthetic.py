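"""Ground-truthed synthetic voltage-imaging recordings.

The generator emulates trial-structured somatic voltage-imaging sessions
recorded at ~828 frames/s during electrical stimulation: a theta-band
(3-12 Hz) subthreshold oscillation, pulse-locked depolarization kernels
summating across a 40 or 140 Hz pulse train, optional 8 Hz optogenetic
depolarization with a soft ceiling, spikes riding on the subthreshold
voltage, photobleaching, shot-like noise and (for movies) frame-to-frame
rigid motion. Every output carries a :class:`GroundTruth` sidecar so each
downstream analysis stage has a known-answer test.

Subthreshold voltage is expressed in *spike-amplitude units*: 1.0 equals the
peak height of an action potential in the same trace, which is also the unit
the analysis reports Vm in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import signal

from .containers import FluorescenceTrace, StimProtocol, VoltageMovie

__all__ = [
    "DbsKernel",
    "OptoConfig",
    "ThetaConfig",
    "SpikeModel",
    "BleachConfig",
    "GeneratorConfig",
    "GroundTruth",
    "generate_protocol",
    "generate_vm_and_spikes",
    "render_trace",
    "render_movie",
    "random_walk_shifts",
    "dbs_scenario",
    "opto_dbs_scenario",
    "soma_template",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class DbsKernel:
    """Single-pulse membrane response: alpha-like difference of exponentials.

    ``k(t) ∝ exp(-(t-latency)/decay) - exp(-(t-latency)/rise)`` for
    ``t > latency``, normalized to peak ``amplitude`` (spike-amplitude
    units). Defaults put the peak ~9 ms after pulse onset so that a 40 Hz
    train repolarizes between pulses while a 140 Hz train summates into a
    plateau.

    A slow depolarization-driven adaptation current is modeled
    subtractively: ``adaptation_strength`` times an exponential low-pass
    (time constant ``adaptation_tau``) of the summed pulse drive is
    subtracted from it. Because the low-pass tracks the *mean* drive, a
    strongly summating train (140 Hz) sags after its early peak while the
    per-pulse modulation of a repolarizing train (40 Hz) is left intact.
    """

    latency: float = 0.003
    rise: float = 0.003
    decay: float = 0.015
    amplitude: float = 0.3
    adaptation_strength: float = 0.5
    adaptation_tau: float = 0.15

    def peak_time(self) -> float:
        """Time from pulse onset to kernel peak, seconds."""
        r, d = self.rise, self.decay
        return self.latency + r * d / (d - r) * np.log(d / r)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Unadapted kernel sampled at times ``t`` (s from pulse onset)."""
        s = np.asarray(t, dtype=float) - self.latency
        raw = np.where(s > 0, np.exp(-np.maximum(s, 0) / self.decay)
                       - np.exp(-np.maximum(s, 0) / self.rise), 0.0)
        speak = self.peak_time() - self.latency
        peak = np.exp(-speak / self.decay) - np.exp(-speak / self.rise)
        return self.amplitude * raw / peak


@dataclass
class OptoConfig:
    """8 Hz optogenetic drive: 42 ms light pulses with exponential rise/decay."""

    frequency: float = 8.0
    pulse_width: float = 0.042
    amplitude: float = 0.0
    rise_tau: float = 0.005
    decay_tau: float = 0.020


@dataclass
class ThetaConfig:
    """Narrowband (3-12 Hz) Gaussian subthreshold oscillation.

    ``amplitude`` is the standard deviation of the band-limited process in
    spike-amplitude units.
    """

    band: tuple[float, float] = (3.0, 12.0)
    amplitude: float = 0.1


@dataclass
class SpikeModel:
    """Spike generation from the noiseless subthreshold voltage.

    ``mode="threshold"`` emits a spike at every upward crossing of
    ``threshold`` (with absolute refractory). ``mode="poisson"`` draws an
    inhomogeneous Poisson train whose rate is a logistic function of the
    voltage, ``max_rate / (1 + exp(-(vm - threshold)/rate_sharpness))``,
    thinned by the refractory period; this keeps neurons spiking when a
    sustained depolarization parks the voltage above threshold.
    """

    mode: str = "threshold"
    threshold: float = 0.18
    refractory: float = 0.005
    waveform: tuple[float, ...] = (0.15, 1.0, 0.12)  # frames pk-1, pk, pk+1
    amplitude: float = 1.0
    max_rate: float = 25.0
    rate_sharpness: float = 0.015


@dataclass
class BleachConfig:
    """Photobleaching trend; ``magnitude`` is the fraction of the baseline
    fluorescence lost over the whole recording."""

    kind: str = "linear"  # linear | exponential
    magnitude: float = 0.1


@dataclass
class GeneratorConfig:
    sampling_rate: float = 828.0
    trial_layout: str = "dbs_only"  # dbs_only | opto_dbs
    n_trials: int = 5
    dbs_frequency: float = 40.0
    dbs_kernel: DbsKernel = field(default_factory=DbsKernel)
    opto: OptoConfig = field(default_factory=OptoConfig)
    theta: ThetaConfig = field(default_factory=ThetaConfig)
    saturation_level: float = np.inf
    spike_model: SpikeModel = field(default_factory=SpikeModel)
    bleach: BleachConfig = field(default_factory=BleachConfig)
    noise_sd: float = 10.0
    gain: float = 100.0  # fluorescence units per spike-amplitude unit
    offset: float = 500.0
    shot_noise: bool = False
    seed: int = 0

    # trial geometry; None -> layout default
    trial_duration: Optional[float] = None
    dbs_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.trial_layout not in ("dbs_only", "opto_dbs"):
            raise ValueError(f"unknown trial layout {self.trial_layout!r}")
        if self.trial_duration is None:
            self.trial_duration = 12.0 if self.trial_layout == "dbs_only" else 3.0
        if self.dbs_window is None:
            self.dbs_window = (2.0, 3.0) if self.trial_layout == "dbs_only" else (1.0, 2.0)
        self.validate()

    def validate(self) -> None:
        if self.dbs_frequency <= 0:
            raise ValueError("dbs_frequency must be positive")
        if 1.0 / self.dbs_frequency < 2.0 / self.sampling_rate:
            raise ValueError(
                "DBS period shorter than 2 frame intervals is unresolvable "
                f"at {self.sampling_rate} Hz sampling"
            )
        highest = max(self.dbs_frequency, self.opto.frequency, self.theta.band[1])
        if self.sampling_rate <= 2 * highest:
            raise ValueError("sampling_rate must exceed twice the highest frequency")
        if self.trial_layout == "opto_dbs" and (
            self.opto.pulse_width >= 1.0 / self.opto.frequency
        ):
            raise ValueError("opto pulse_width must be below the inter-pulse interval")
        wf_width = len(self.spike_model.waveform) / self.sampling_rate
        if self.spike_model.refractory <= wf_width:
            raise ValueError("refractory must exceed the spike waveform width")

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj
        return clean(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key, sub in (("dbs_kernel", DbsKernel), ("opto", OptoConfig),
                         ("theta", ThetaConfig), ("spike_model", SpikeModel),
                         ("bleach", BleachConfig)):
            if key in d and isinstance(d[key], dict):
                dd = dict(d[key])
                if key == "theta" and "band" in dd:
                    dd["band"] = tuple(dd["band"])
                if key == "spike_model" and "waveform" in dd:
                    dd["waveform"] = tuple(dd["waveform"])
                d[key] = sub(**dd)
        if d.get("dbs_window") is not None:
            d["dbs_window"] = tuple(d["dbs_window"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Noiseless generator state backing a rendered trace or movie."""

    true_vm: np.ndarray                 # spike-amplitude units, saturated
    true_spike_frames: np.ndarray
    true_spike_amplitude: float         # spike-amplitude units (== 1·amplitude)
    true_bleach: np.ndarray             # fluorescence units
    true_shifts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.true_vm = np.asarray(self.true_vm, dtype=float)
        self.true_spike_frames = np.asarray(self.true_spike_frames, dtype=int)
        if self.true_spike_frames.size > 1 and np.any(np.diff(self.true_spike_frames) <= 0):
            raise ValueError("spike frames must be strictly increasing")


# --------------------------------------------------------------------------
# protocol
# --------------------------------------------------------------------------

def generate_protocol(config: GeneratorConfig) -> StimProtocol:
    """Build the stimulation protocol implied by the configured trial layout.

    DBS pulses fill the 1 s stimulation window at the exact inter-pulse
    interval ``1/f``; in the ``opto_dbs`` layout, light-pulse onsets tile the
    whole 3 s trial at the optogenetic rate.
    """
    config.validate()
    lo, hi = config.dbs_window
    n_pulses = int(round((hi - lo) * config.dbs_frequency))
    pulse_times = lo + np.arange(n_pulses) / config.dbs_frequency
    opto_onsets = np.empty(0)
    opto_freq = None
    if config.trial_layout == "opto_dbs":
        n_opto = int(np.ceil(config.trial_duration * config.opto.frequency - 1e-9))
        opto_onsets = np.arange(n_opto) / config.opto.frequency
        opto_freq = config.opto.frequency
    return StimProtocol(
        n_trials=config.n_trials,
        trial_duration=config.trial_duration,
        dbs_window=(lo, hi),
        dbs_frequency=config.dbs_frequency,
        dbs_pulse_times=pulse_times,
        opto_onsets=opto_onsets,
        opto_pulse_width=config.opto.pulse_width,
        opto_frequency=opto_freq,
    )


# --------------------------------------------------------------------------
# subthreshold voltage and spikes
# --------------------------------------------------------------------------

def _narrowband_theta(n: int, fs: float, band: tuple[float, float],
                      amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.zeros(n)
    white = rng.standard_normal(n + 2000)  # pad to wash out filter transients
    sos = signal.butter(2, [band[0] / (fs / 2), band[1] / (fs / 2)],
                        btype="bandpass", output="sos")
    x = signal.sosfiltfilt(sos, white)[1000:1000 + n]
    sd = x.std()
    return amplitude * x / sd if sd > 0 else np.zeros(n)


def _pulse_train_component(times: np.ndarray, onsets: np.ndarray,
                           kernel_fn, support: float) -> np.ndarray:
    """Sum a per-pulse kernel over pulse onsets (finite kernel support)."""
    out = np.zeros_like(times)
    if onsets.size == 0:
        return out
    dt = times[1] - times[0] if times.size > 1 else 1.0
    n_support = int(np.ceil(support / dt))
    for onset in onsets:
        i0 = int(np.searchsorted(times, onset))
        i1 = min(i0 + n_support, times.size)
        if i0 >= times.size:
            continue
        out[i0:i1] += kernel_fn(times[i0:i1] - onset)
    return out


def _dbs_component(times: np.ndarray, protocol: StimProtocol,
                   config: GeneratorConfig) -> np.ndarray:
    kern = config.dbs_kernel
    if kern.amplitude == 0:
        return np.zeros_like(times)
    drive = np.zeros_like(times)
    dt = times[1] - times[0] if times.size > 1 else 1.0
    support = kern.latency + 8 * kern.decay
    n_support = int(np.ceil(support / dt))
    for onset in protocol.absolute_dbs_pulse_times():
        i0 = int(np.searchsorted(times, onset))
        i1 = min(i0 + n_support, times.size)
        if i0 >= times.size:
            continue
        drive[i0:i1] += kern.evaluate(times[i0:i1] - onset)
    a = kern.adaptation_strength
    if a:
        alpha = dt / kern.adaptation_tau
        adaptation = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], drive)
        return drive - a * adaptation
    return drive


def _opto_kernel(config: OptoConfig):
    w, tr, td, amp = (config.pulse_width, config.rise_tau,
                      config.decay_tau, config.amplitude)

    def k(t):
        t = np.asarray(t, dtype=float)
        during = amp * (1.0 - np.exp(-np.clip(t, 0, None) / tr))
        end_level = amp * (1.0 - np.exp(-w / tr))
        after = end_level * np.exp(-np.clip(t - w, 0, None) / td)
        return np.where(t < w, during, after) * (t >= 0)

    return k


def soft_saturate(v: np.ndarray, level: float) -> np.ndarray:
    """Smooth ceiling ``level·tanh(v/level)``; identity when level is inf."""
    if not np.isfinite(level):
        return np.asarray(v, dtype=float)
    return level * np.tanh(np.asarray(v, dtype=float) / level)


def _threshold_spikes(vm: np.ndarray, threshold: float, refractory_frames: int) -> np.ndarray:
    above = vm >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    return _enforce_refractory(crossings, refractory_frames)


def _poisson_spikes(vm: np.ndarray, model: SpikeModel, fs: float,
                    rng: np.random.Generator, refractory_frames: int) -> np.ndarray:
    rate = model.max_rate / (1.0 + np.exp(-(vm - model.threshold) / model.rate_sharpness))
    p = np.clip(rate / fs, 0, 1)
    candidates = np.flatnonzero(rng.random(vm.size) < p)
    return _enforce_refractory(candidates, refractory_frames)


def _enforce_refractory(frames: np.ndarray, refractory_frames: int) -> np.ndarray:
    kept: list[int] = []
    last = -np.inf
    for f in frames:
        if f - last >= refractory_frames:
            kept.append(int(f))
            last = f
    return np.asarray(kept, dtype=int)


def generate_vm_and_spikes(config: GeneratorConfig,
                           protocol: Optional[StimProtocol] = None) -> GroundTruth:
    """Simulate the noiseless subthreshold voltage and the spike train.

    The voltage is ``soft_saturate(theta + DBS kernel train + opto train)``
    in spike-amplitude units (resting level 0); saturation is applied before
    spike generation so that depolarization toward the ceiling also
    compresses the oscillatory components, emulating the ceiling effect seen
    when strong stimulation rides on optogenetic depolarization.
    """
    config.validate()
    if protocol is None:
        protocol = generate_protocol(config)
    fs = config.sampling_rate
    n = protocol.n_frames(fs)
    times = np.arange(n) / fs

    rng_theta = np.random.default_rng([config.seed, 11])
    vm = _narrowband_theta(n, fs, config.theta.band, config.theta.amplitude, rng_theta)
    vm = vm + _dbs_component(times, protocol, config)
    if config.opto.amplitude and protocol.opto_onsets.size:
        k = _opto_kernel(config.opto)
        support = config.opto.pulse_width + 8 * config.opto.decay_tau
        vm = vm + _pulse_train_component(
            times, protocol.absolute_opto_onsets(), k, support)
    vm = soft_saturate(vm, config.saturation_level)

    refr = max(1, int(round(config.spike_model.refractory * fs)))
    if config.spike_model.mode == "threshold":
        spikes = _threshold_spikes(vm, config.spike_model.threshold, refr)
    elif config.spike_model.mode == "poisson":
        rng_sp = np.random.default_rng([config.seed, 23])
        spikes = _poisson_spikes(vm, config.spike_model, fs, rng_sp, refr)
    else:
        raise ValueError(f"unknown spike model mode {config.spike_model.mode!r}")
    # keep spikes whose rendered waveform fits inside the trace
    spikes = spikes[(spikes >= 3) & (spikes < n - 1)]

    duration = n / fs
    if config.bleach.kind == "linear":
        bleach = -config.bleach.magnitude * config.offset * (times / duration)
    elif config.bleach.kind == "exponential":
        bleach = config.offset * (np.exp(-config.bleach.magnitude * times / duration) - 1.0)
    else:
        raise ValueError(f"unknown bleach kind {config.bleach.kind!r}")

    return GroundTruth(
        true_vm=vm,
        true_spike_frames=spikes,
        true_spike_amplitude=config.spike_model.amplitude,
        true_bleach=bleach,
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_trace(truth: GroundTruth, config: GeneratorConfig,
                 protocol: Optional[StimProtocol] = None) -> FluorescenceTrace:
    """Render a fluorescence trace: ``offset + gain·(vm + spikes) + bleach + noise``.

    Spikes are rendered as a 3-frame waveform (one dominant frame, matching
    ~1 ms action potentials undersampled at 828 Hz) whose peak height is
    ``gain·spike_model.amplitude`` above the concurrent subthreshold value.
    """
    if protocol is None:
        protocol = generate_protocol(config)
    n = truth.true_vm.size
    values = truth.true_vm.copy()
    wf = np.asarray(config.spike_model.waveform, dtype=float)
    half = len(wf) // 2
    for f in truth.true_spike_frames:
        lo = f - half
        for j, w in enumerate(wf):
            idx = lo + j
            if 0 <= idx < n:
                values[idx] += w * truth.true_spike_amplitude
    values = config.offset + config.gain * values + truth.true_bleach

    if config.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if config.noise_sd == 0:
        warnings.warn("noise_sd = 0: rendered trace is noiseless; any "
                      "requested SBR is unattainable/undefined")
    rng = np.random.default_rng([config.seed, 37])
    if config.shot_noise:
        # photon-shot limit: variance proportional to intensity, scaled so the
        # baseline-intensity SD equals noise_sd
        lam = np.clip(values, 1e-9, None)
        scale = config.noise_sd ** 2 / max(config.offset, 1e-9)
        values = rng.poisson(lam / scale) * scale
    elif config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=n)

    return FluorescenceTrace(
        values=values,
        sampling_rate=config.sampling_rate,
        trial_boundaries=protocol.trial_boundaries(config.sampling_rate),
        protocol=protocol,
    )


def soma_template(shape: tuple[int, int], diameter: float = 15.0,
                  center: Optional[tuple[float, float]] = None) -> np.ndarray:
    """2-D Gaussian disc soma template, peak 1, FWHM ≈ ``diameter`` pixels."""
    ny, nx = shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    sigma = diameter / 2.355  # FWHM -> sigma
    y, x = np.mgrid[0:ny, 0:nx]
    return np.exp(-(((y - center[0]) ** 2 + (x - center[1]) ** 2) / (2 * sigma ** 2)))


def random_walk_shifts(n_frames: int, max_step: int = 1, max_abs: int = 10,
                       seed: int = 0) -> np.ndarray:
    """Integer-pixel random-walk rigid shifts, reflected at ±``max_abs``."""
    rng = np.random.default_rng([seed, 53])
    steps = rng.integers(-max_step, max_step + 1, size=(n_frames, 2))
    steps[0] = 0
    walk = np.cumsum(steps, axis=0)
    return np.clip(walk, -max_abs, max_abs).astype(int)


def render_movie(truth: GroundTruth, config: GeneratorConfig,
                 shape: tuple[int, int] = (96, 96),
                 shifts: Optional[np.ndarray] = None,
                 background: float = 10.0,
                 pixel_noise_sd: float = 2.0,
                 protocol: Optional[StimProtocol] = None) -> tuple[VoltageMovie, GroundTruth]:
    """Render an image stack: a translated soma template scaled per frame.

    Each frame is ``background + intensity_t · template(shifted) + noise``
    where ``intensity_t`` is the rendered fluorescence trace scaled to the
    template peak. Shifts must be integer pixels with ``|shift| ≤ shape/4``;
    the returned :class:`GroundTruth` has ``true_shifts`` filled in.
    """
    if protocol is None:
        protocol = generate_protocol(config)
    trace = render_trace(truth, config, protocol)
    n = trace.n_frames
    if shifts is None:
        shifts = np.zeros((n, 2), dtype=int)
    shifts = np.asarray(shifts)
    if shifts.shape != (n, 2):
        raise ValueError("shifts must be (n_frames, 2)")
    if not np.issubdtype(shifts.dtype, np.integer):
        if not np.allclose(shifts, np.round(shifts)):
            raise ValueError("generator emits integer pixel shifts only")
        shifts = np.round(shifts).astype(int)
    limit = min(shape) / 4.0
    if np.abs(shifts).max(initial=0) > limit:
        raise ValueError(f"|shift| must be ≤ shape/4 = {limit}")

    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    intensity = trace.values / trace.values.mean()
    rng = np.random.default_rng([config.seed, 71])
    frames = np.empty((n, ny, nx))
    for i in range(n):
        tpl = soma_template(shape, center=(cy + shifts[i, 0], cx + shifts[i, 1]))
        frames[i] = background + 50.0 * intensity[i] * tpl
    if pixel_noise_sd > 0:
        frames += rng.normal(0.0, pixel_noise_sd, size=frames.shape)

    movie = VoltageMovie(frames=frames, sampling_rate=config.sampling_rate,
                         trial_boundaries=protocol.trial_boundaries(config.sampling_rate))
    truth_out = GroundTruth(
        true_vm=truth.true_vm,
        true_spike_frames=truth.true_spike_frames,
        true_spike_amplitude=truth.true_spike_amplitude,
        true_bleach=truth.true_bleach,
        true_shifts=shifts,
    )
    return movie, truth_out


# --------------------------------------------------------------------------
# canonical study scenarios
# --------------------------------------------------------------------------

def _calibrate_for_sbr(config: GeneratorConfig, target_sbr: float,
                       theta_fraction: float = 0.6) -> GeneratorConfig:
    """Set theta amplitude and noise so the rendered trace has ~``target_sbr``.

    The subthreshold SD is split into a theta-band share (``theta_fraction``
    of the variance) and white noise; the spike amplitude is then
    ``target_sbr`` subthreshold SDs. Across-neuron SBR differences are thus
    modeled as spike-amplitude variation, the dominant source of SBR spread
    in voltage imaging where ~1 ms spikes are undersampled frame to frame.
    """
    if not (0 < theta_fraction < 1):
        raise ValueError("theta_fraction must be in (0, 1)")
    if target_sbr <= 0:
        warnings.warn("non-positive target SBR is unattainable; leaving config unchanged")
        return config
    sub_sd_vm = 1.0 / target_sbr  # subthreshold SD in spike-amplitude units
    config.theta.amplitude = np.sqrt(theta_fraction) * sub_sd_vm
    config.noise_sd = config.gain * np.sqrt(1 - theta_fraction) * sub_sd_vm
    return config


def dbs_scenario(dbs_frequency: float = 40.0, n_trials: int = 5,
                 target_sbr: float = 6.0, seed: int = 0,
                 spike_mode: str = "threshold",
                 kernel_amplitude: float = 0.35,
                 saturation_level: float = 0.45) -> GeneratorConfig:
    """Canonical DBS-only session: 1 s stimulation per 12 s trial.

    The soft voltage ceiling sits well above the spike threshold, so it
    barely touches baseline dynamics but compresses theta riding on the
    stimulation-evoked depolarization — the regime in which stimulation
    captures spike timing from the ongoing theta rhythm.
    """
    cfg = GeneratorConfig(
        trial_layout="dbs_only",
        n_trials=n_trials,
        dbs_frequency=dbs_frequency,
        saturation_level=saturation_level,
        seed=seed,
    )
    cfg.dbs_kernel.amplitude = kernel_amplitude
    cfg.spike_model.mode = spike_mode
    return _calibrate_for_sbr(cfg, target_sbr)


def opto_dbs_scenario(dbs_frequency: float = 40.0, n_trials: int = 20,
                      target_sbr: float = 6.0, seed: int = 0,
                      kernel_amplitude: float = 0.6,
                      opto_amplitude: float = 0.4,
                      saturation_level: float = 0.8) -> GeneratorConfig:
    """Canonical optogenetics+DBS session: 3 s trials, 8 Hz light pulses
    throughout, 1 s DBS in the middle, soft voltage ceiling on.

    Spiking uses the Poisson rate model: with the ceiling holding the voltage
    near saturation during stimulation, a deterministic threshold crossing
    would silence the train, whereas real neurons keep firing with degraded
    timing.
    """
    cfg = GeneratorConfig(
        trial_layout="opto_dbs",
        n_trials=n_trials,
        dbs_frequency=dbs_frequency,
        saturation_level=saturation_level,
        seed=seed,
    )
    cfg.dbs_kernel.amplitude = kernel_amplitude
    cfg.opto.amplitude = opto_amplitude
    cfg.spike_model.mode = "poisson"
    return _calibrate_for_sbr(cfg, target_sbr)
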