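# Methods

This note documents the models and numerical choices behind `voltstim`: what
the synthetic generator simulates and why, how each analysis stage is
defined, where the design was genuinely open, and what the passing test
suite does and does not establish about real recordings.

## Recording model

A session is a sequence of identical trials sampled at 828 frames/s (the
camera rate of the high-speed voltage-imaging rig this analysis targets).
Two canonical layouts are built in:

* **dbs_only** — 12 s trials with a 1 s electrical stimulation window
  (default at 2–3 s into the trial); pulses fill the window at exactly the
  inter-pulse interval 1/f (40 pulses at 40 Hz; 140 at 140 Hz, spacing
  ≈ 7.1 ms).
* **opto_dbs** — 3 s trials with 8 Hz optogenetic light pulses (42 ms wide)
  tiling the whole trial and the electrical train occupying the middle
  second.

All analysis operates on the concatenated recording with trial boundaries
carried alongside.

## The synthetic voltage

Subthreshold voltage is expressed in *spike-amplitude units* (1.0 = the
peak height of an action potential in the same trace), which is also the
unit the analysis reports Vm in, so generator truth and pipeline output are
directly comparable. The noiseless voltage is

```
vm(t) = sat( theta(t) + dbs(t) + opto(t) )
```

* **theta(t)** — band-limited Gaussian noise (order-2 Butterworth band-pass
  of white noise, 3–12 Hz), scaled to a target SD. This emulates the
  prominent hippocampal theta oscillation that paces CA1 subthreshold
  voltage; it is a stationary surrogate, not a model of behavioral state.
* **dbs(t)** — each electrical pulse contributes an alpha-like kernel
  (difference of exponentials; latency 3 ms, rise 3 ms, decay 15 ms, peak
  ≈ 9 ms after pulse onset, default peak amplitude 0.3–0.35 spike units in
  the canonical scenarios). With these time constants a 40 Hz train
  repolarizes most of the way between pulses while a 140 Hz train summates
  into a plateau several times the single-pulse peak — the central
  frequency-dependence the analysis must resolve. A slow
  **adaptation current** is modeled subtractively: 0.5 × an exponential
  low-pass (τ = 150 ms) of the summed pulse drive. Because the low-pass
  tracks the mean drive, the strongly summating 140 Hz train sags after an
  early peak (transient > sustained) while the per-pulse modulation of the
  40 Hz train is untouched. A multiplicative per-pulse envelope was tried
  first and rejected: any strength sufficient to produce the 140 Hz sag
  also flattened the 40 Hz per-pulse modulation and destroyed
  stimulation-frequency spike locking.
* **opto(t)** — each light pulse contributes an exponential rise
  (τ = 5 ms) toward its amplitude for 42 ms, then an exponential decay
  (τ = 20 ms).
* **sat(·)** — a smooth ceiling `L·tanh(v/L)`. This one nonlinearity
  produces the "ceiling" phenomenology: depolarization toward the ceiling
  compresses whatever rides on it (theta, the 8 Hz optogenetic response),
  linking evoked depolarization to entrainment suppression. It is odd
  (hyperpolarization compresses symmetrically), which is a simplification.
  `d/dL [L tanh(v/L)] ≥ 0`, so raising the ceiling never decreases evoked
  modulation — a tested invariant.

## Spikes

Two generative modes:

* **threshold** (default) — a spike at every upward crossing of a fixed
  voltage threshold, with an absolute refractory period (5 ms). Simple and
  deterministic; appropriate when the voltage fluctuates across threshold.
* **poisson** — an inhomogeneous Poisson train with logistic rate
  `max_rate / (1 + exp(-(vm - θ)/Δ))` (defaults 25 Hz, θ = 0.18, Δ = 0.015
  spike units), thinned by the refractory period. The canonical
  entrainment and optogenetic scenarios use this mode because a sustained
  plateau above threshold silences a deterministic threshold-crosser,
  whereas real neurons keep firing there with degraded timing. The sharp
  logistic makes the rate saturate at pulse-kernel crests, so *which* 40 Hz
  cycle fires is nearly independent of theta — the regime in which
  stimulation captures spike timing from the ongoing rhythm.

Rendering adds spikes as a 3-frame waveform (relative amplitudes 0.15 /
1.0 / 0.12) — a ~1 ms action potential undersampled at 1.21 ms frames is
essentially one dominant frame — then applies gain, offset, linear
photobleaching (10% of baseline per recording by default; exponential
available) and white Gaussian noise (Poisson shot noise behind a flag).

### SBR calibration

A requested SBR is realized by fixing the subthreshold composition — 60%
of the subthreshold *variance* in the theta band, 40% white — and setting
the spike gain to SBR × subthreshold SD. Across-neuron SBR variation is
thus modeled as spike-amplitude variation, which is how voltage-imaging
SBR actually varies (frame-phase-dependent attenuation of undersampled
spikes, soma-targeting quality), rather than as noise-level variation,
which would make low-SBR traces white-noise-dominated in a way real
recordings are not. Realized SBR tracks requests within ~±15% for requests
≥ 5; below ~5 the amplitude statistic's noise bias (see below) inflates it
further.

## Analysis stages

* **Motion correction** — each frame's displacement maximizes the
  zero-padded FFT cross-correlation with a reference image (default: mean
  frame of the concatenated recording; `first` or an explicit array
  available), search capped at ±20 px, optional parabolic subpixel
  refinement. Note that a mean-frame reference determines shifts only up
  to a global constant (its centroid reflects the shift distribution);
  ground-truth recovery tests therefore anchor on the first frame.
  Correction translates by the negated shift, filling exposed borders with
  the frame median. ROI traces are unweighted means over mask pixels.
* **Detrending** — each stimulation window is replaced by the mean of the
  10 frames before onset and 10 after offset; a least-squares line is
  fitted to that interpolated trace and subtracted from the *original*, so
  stimulation-evoked depolarization survives while the window provably
  cannot influence the fit (a perturbation-tested invariant).
* **Spike detection** — the detrended trace is high-pass filtered above
  120 Hz (zero-phase order-4 Butterworth; a unit impulse retains ~0.71 of
  its peak, the brickwall limit at this cutoff). Frames exceeding 4× the
  baseline fluctuation of the high-passed trace are collapsed per
  contiguous run to the local maximum; peaks closer than 2 frames merge.
  The baseline-fluctuation estimator smooths with a ±100-frame moving mean
  (truncated at edges), clips values above the smoothed trace (removing
  positive-going spikes), and returns
  `sqrt( var(smoothed) + 2·mean((clipped − smoothed)²) )` — the factor 2
  undoes the one-sided clipping so a spike-free Gaussian trace returns
  exactly its own SD and pure-noise false positives sit at the Gaussian
  4σ tail (≈ 0.3 per 10⁴ frames). A doubly-smoothed variant returning the
  slow-fluctuation SD is available behind a flag.
* **Amplitude & SBR** — amplitude = peak minus the minimum of the 3 frames
  before the peak, on the detrended (not high-passed) trace; this statistic
  carries a positive bias of roughly one fast-noise SD on noisy traces,
  which is inherent to its definition and left uncorrected. SBR = mean
  amplitude / SD of the spike-removed trace.
* **Vm** — 3 frames centered on each peak are replaced by linear
  interpolation between the nearest untouched neighbors (overlaps merge;
  idempotent); division by mean spike amplitude; optional per-trial
  subtraction of the 1 s pre-onset baseline mean. Windows: transient
  0–0.15 s, sustained 0.15–1 s, post = 1 s after offset. Per-trial means
  first, then across trials (and across neurons with SEM at the population
  level).
* **Firing rate** — frame-resolution indicator × rate, convolved with a
  unit-area rectangular kernel (default 25 ms for analysis; 300 ms only in
  plotting).
* **Spectral** — power from a unit-energy 5-cycle complex Morlet transform
  (implemented directly via FFT convolution; frequencies whose 5 cycles do
  not fit the trace are dropped with a warning). Band phase from an
  order-2 Butterworth band-pass (±2 Hz, centers on a 2 Hz grid) and the
  analytic-signal angle, cosine convention (phase 0 at the band-passed
  peak). Stimulation-band power change is reported as the stim/baseline
  ratio (difference also returned).
* **PLV** — modulus of the mean resultant vector; single-neuron values are
  gated at > 5 spikes; population mode concatenates spikes across neurons
  with provenance. Bootstrap SD resamples spikes with replacement (note:
  near PLV = 0 the modulus fold inflates single-sample bootstrap SDs by up
  to ~1.5×; the estimator is calibrated for concentrated phase sets).
  Permutation inference redraws the same number of spike frames uniformly
  within the analysis window (circular time-shift behind a flag) and uses
  p = (1 + #{null ≥ observed}) / (1 + replicates); the test is exactly
  rank-based and holds its nominal level (verified at 5% over large null
  simulations).
* **Event alignment** — native frame resolution (~1.21 ms), no upsampling
  (the camera cannot resolve the sub-millisecond biphasic pulse waveform
  itself). Events whose lag window crosses a trial boundary are dropped
  and counted. Pre-onset normalization windows: 10 ms before 40 Hz pulses,
  5 ms before 140 Hz pulses, 50 ms before light pulses. Per-lag onset
  tests are reported both as uncorrected per-lag paired t-tests (α = 0.05)
  and as the first 2-SD crossing of the baseline-lag distribution;
  Benjamini–Hochberg correction is available and off by default. Display
  smoothing lives only in plotting utilities.
* **Comparisons** — two-sided paired (df = n−1) or independent t-tests;
  label-permutation alternative for bounded statistics like PLV.

## Problem sizes

Validation runs use sizes chosen to make every check statistically sharp at
interactive runtimes: 50 five-trial (60 s) traces spanning SBR 5–8 for the
detection operating point; a 200-frame 96×96 movie with a ±20 px random
walk for shift recovery; 8-trial sessions for the 40 vs 140 Hz
phenomenology; 40 synthetic neurons (kernel amplitudes uniform on 0.1–1.0,
both stimulation frequencies, as a pooled cohort) for the
depolarization-vs-suppression regression; 1000 null simulations for each
type-I-error check.

## What passing tests do and do not show

The generator reproduces the *structure* the analysis assumes — trial
layout, theta-band subthreshold dynamics, pulse-kernel summation, a
voltage ceiling, undersampled spikes, bleaching, noise, rigid motion — so
passing tests demonstrate that each stage measures what it claims on data
with known answers, and that the directional phenomenology (40 Hz per-pulse
entrainment vs 140 Hz plateau; theta capture; saturation-mediated
suppression of 8 Hz responses scaling with depolarization) is recovered
end to end. They do not validate biophysical mechanism: the kernel,
adaptation current, logistic rate and tanh ceiling are phenomenological;
real recordings add non-rigid motion, dendritic contamination,
non-stationary theta, correlated network input and indicator nonlinearity,
none of which are simulated. Population statistics on real neurons are
reproduced in form, not in value.

## Known limitations

* The amplitude statistic's noise bias makes realized SBR overshoot
  requests below ~5.
* Harmonics: the non-sinusoidal stimulation cycle produces spike-phase
  locking at harmonics of the drive (80/120/160 Hz for a 40 Hz train)
  comparable to the fundamental; analyses asserting a stimulation-frequency
  peak treat harmonic bins as part of the entrainment structure.
* The tanh ceiling saturates hyperpolarization symmetrically.
* Detrending fits one line to the concatenated recording (per-trial lines
  behind a flag); strong nonlinear bleaching would leave residual trend.
* Shift estimation is integer-pixel by default; subpixel refinement is a
  flag, and non-rigid deformation is out of scope.
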