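"""Generator correctness: protocol arithmetic, kernel superposition physics,
spike-train validity, rendering determinism and SBR calibration."""

import numpy as np
import pytest

import voltstim as vs
from voltstim.synthetic import (DbsKernel, GeneratorConfig, dbs_scenario,
                                generate_protocol, generate_vm_and_spikes,
                                opto_dbs_scenario, render_movie, render_trace,
                                soft_saturate)

FS = 828.0


class TestProtocol:
    def test_40hz_pulse_count_and_spacing(self):
        cfg = GeneratorConfig(dbs_frequency=40.0)
        prot = generate_protocol(cfg)
        assert prot.dbs_pulse_times.size == 40
        assert np.allclose(np.diff(prot.dbs_pulse_times), 0.025)

    def test_140hz_second_pulse_at_7p1_ms(self):
        prot = generate_protocol(GeneratorConfig(dbs_frequency=140.0))
        assert prot.dbs_pulse_times.size == 140
        gap_ms = (prot.dbs_pulse_times[1] - prot.dbs_pulse_times[0]) * 1e3
        assert gap_ms == pytest.approx(7.1, abs=0.05)

    def test_opto_layout_onsets_and_window(self):
        # brute enumeration: 8 Hz onsets strictly inside a 3 s trial -> 24
        cfg = GeneratorConfig(trial_layout="opto_dbs")
        prot = generate_protocol(cfg)
        expected = [k / 8.0 for k in range(100) if k / 8.0 < 3.0]
        assert prot.opto_onsets.tolist() == expected
        assert len(expected) == 24
        assert prot.dbs_window == (1.0, 2.0)
        assert prot.opto_pulse_width == pytest.approx(0.042)

    def test_unresolvable_frequency_rejected(self):
        with pytest.raises(ValueError, match="unresolvable|exceed twice"):
            GeneratorConfig(dbs_frequency=500.0)

    def test_pulses_inside_window(self):
        prot = generate_protocol(GeneratorConfig(dbs_frequency=140.0))
        lo, hi = prot.dbs_window
        assert prot.dbs_pulse_times.min() >= lo
        assert prot.dbs_pulse_times.max() < hi


class TestVmAndSpikes:
    def test_all_amplitudes_zero_gives_flat_vm_no_spikes(self):
        cfg = GeneratorConfig(n_trials=1, seed=0)
        cfg.dbs_kernel.amplitude = 0.0
        cfg.theta.amplitude = 0.0
        truth = generate_vm_and_spikes(cfg)
        assert np.allclose(truth.true_vm, 0.0)
        assert truth.true_spike_frames.size == 0

    def test_kernel_superposition_40_repolarizes_140_plateaus(self):
        """Independent oracle: evaluate the saturated kernel superposition on
        a fine grid; 40 Hz repolarizes between pulses (> 50% of the
        single-pulse peak) while 140 Hz summates into a near-flat plateau
        (< 20% of the single-pulse peak) whose mean exceeds no-stim Vm."""
        kern = DbsKernel(amplitude=0.35)
        sat = 0.45
        t = np.arange(0.0, 1.0, 1e-4)
        for freq, check in ((40.0, "mod_large"), (140.0, "mod_small")):
            drive = np.zeros_like(t)
            for p in np.arange(0.0, 1.0, 1.0 / freq):
                drive += kern.evaluate(t - p)
            # steady-state adaptation subtracts the running mean of the drive
            late = drive - kern.adaptation_strength * drive[t > 0.5].mean()
            vm = sat * np.tanh(late / sat)
            seg = vm[(t >= 0.6) & (t < 0.6 + 1.0 / freq)]
            modulation = seg.max() - seg.min()
            if check == "mod_large":
                assert modulation > 0.5 * kern.amplitude
            else:
                assert modulation < 0.2 * kern.amplitude
                assert seg.mean() > 0.1  # depolarized plateau

        # the generated true_vm reproduces the oracle's modulation contrast
        mods = {}
        for freq in (40.0, 140.0):
            cfg = dbs_scenario(freq, n_trials=1, seed=3, spike_mode="poisson")
            cfg.theta.amplitude = 0.0
            truth = generate_vm_and_spikes(cfg)
            fs = cfg.sampling_rate
            onset = int(round(cfg.dbs_window[0] * fs))
            seg = truth.true_vm[onset + int(0.6 * fs):
                                onset + int(0.6 * fs) + int(round(fs / freq)) + 1]
            mods[freq] = seg.max() - seg.min()
        assert mods[40.0] > 0.5 * 0.35
        assert mods[140.0] < 0.2 * 0.35

    def test_spike_train_validity_invariants(self, short_dbs_session):
        cfg, protocol, truth, _ = short_dbs_session
        refr = int(round(cfg.spike_model.refractory * cfg.sampling_rate))
        isi = np.diff(truth.true_spike_frames)
        assert truth.true_spike_frames.size > 10
        assert np.all(isi >= refr)
        assert truth.true_spike_frames.min() >= 0
        assert truth.true_spike_frames.max() < truth.true_vm.size

    def test_entrainment_by_construction(self):
        """With theta off and the kernel on, the dominant Fourier component
        of true Vm inside the stim window is the stimulation frequency."""
        cfg = dbs_scenario(40.0, n_trials=1, seed=7)
        cfg.theta.amplitude = 0.0
        prot = vs.generate_protocol(cfg)
        truth = generate_vm_and_spikes(cfg, prot)
        (a, b), = prot.dbs_window_frames(cfg.sampling_rate)
        seg = truth.true_vm[a:b] - truth.true_vm[a:b].mean()
        freqs = np.fft.rfftfreq(seg.size, 1 / cfg.sampling_rate)
        spec = np.abs(np.fft.rfft(seg))
        sel = freqs > 5  # skip the slow adaptation envelope
        assert freqs[sel][np.argmax(spec[sel])] == pytest.approx(40.0, abs=1.5)

    def test_saturation_monotonicity(self):
        """Raising the ceiling never decreases opto pulse-evoked modulation."""
        mods = []
        for level in (0.4, 0.8, 1.6):
            cfg = opto_dbs_scenario(40.0, n_trials=1, seed=5,
                                    saturation_level=level)
            cfg.theta.amplitude = 0.0
            truth = generate_vm_and_spikes(cfg)
            fs = cfg.sampling_rate
            seg = truth.true_vm[:int(0.9 * fs)]  # pre-DBS opto cycles
            mods.append(seg.max() - seg.min())
        assert mods[0] <= mods[1] <= mods[2]

    def test_soft_saturate_identity_when_infinite(self, rng):
        v = rng.normal(size=100)
        assert np.allclose(soft_saturate(v, np.inf), v)
        assert np.all(np.abs(soft_saturate(v * 10, 0.5)) <= 0.5)


class TestRendering:
    def test_same_seed_bit_identical(self):
        cfg = dbs_scenario(40.0, n_trials=1, seed=42)
        a = render_trace(generate_vm_and_spikes(cfg), cfg)
        b = render_trace(generate_vm_and_spikes(cfg), cfg)
        assert np.array_equal(a.values, b.values)

    def test_noiseless_render_is_affine_in_vm(self):
        cfg = GeneratorConfig(n_trials=1, seed=0, noise_sd=0.0)
        cfg.bleach.magnitude = 0.0
        cfg.spike_model.threshold = 10.0  # no spikes
        truth = generate_vm_and_spikes(cfg)
        with pytest.warns(UserWarning, match="noiseless"):
            trace = render_trace(truth, cfg)
        assert np.allclose(trace.values,
                           cfg.offset + cfg.gain * truth.true_vm)

    @pytest.mark.parametrize("requested", [5.0, 6.0, 9.0])
    def test_realized_sbr_tracks_request(self, requested):
        """Monte-Carlo over seeds: measured SBR within 25% of requested."""
        measured = []
        for seed in range(10):
            cfg = dbs_scenario(40.0, n_trials=2, target_sbr=requested,
                               seed=1000 + seed)
            prot = vs.generate_protocol(cfg)
            truth = generate_vm_and_spikes(cfg, prot)
            det = vs.detrend_trace(render_trace(truth, cfg, prot), prot)
            spikes = vs.detect_spikes(det)
            report = vs.compute_sbr(det, spikes)
            measured.append(report.sbr)
        assert np.mean(measured) == pytest.approx(requested, rel=0.25)


class TestMovie:
    def test_zero_shift_movie_is_template_times_intensity(self):
        cfg = GeneratorConfig(n_trials=1, trial_duration=0.1,
                              dbs_window=(0.02, 0.05), seed=2, noise_sd=10.0)
        prot = vs.generate_protocol(cfg)
        truth = generate_vm_and_spikes(cfg, prot)
        movie, truth2 = render_movie(truth, cfg, shape=(64, 64),
                                     pixel_noise_sd=0.0, protocol=prot)
        tpl = vs.synthetic.soma_template((64, 64))
        trace = render_trace(truth, cfg, prot)
        intensity = trace.values / trace.values.mean()
        expect = 10.0 + 50.0 * intensity[3] * tpl
        assert np.allclose(movie.frames[3], expect)
        assert np.array_equal(truth2.true_shifts, np.zeros((movie.n_frames, 2)))

    def test_single_frame_shift_detected_by_brute_correlation(self):
        cfg = GeneratorConfig(n_trials=1, trial_duration=0.05,
                              dbs_window=(0.01, 0.02), seed=2)
        prot = vs.generate_protocol(cfg)
        truth = generate_vm_and_spikes(cfg, prot)
        n = truth.true_vm.size
        shifts = np.zeros((n, 2), dtype=int)
        shifts[1] = (3, -2)
        movie, _ = render_movie(truth, cfg, shape=(64, 64), shifts=shifts,
                                pixel_noise_sd=0.0, protocol=prot)
        # brute-force 2-D correlation over integer lags
        ref, img = movie.frames[0], movie.frames[1]
        best, best_v = None, -np.inf
        for dy in range(-5, 6):
            for dx in range(-5, 6):
                v = (np.roll(np.roll(img, -dy, 0), -dx, 1) * ref).sum()
                if v > best_v:
                    best, best_v = (dy, dx), v
        assert best == (3, -2)

    def test_non_integer_shifts_rejected(self):
        cfg = GeneratorConfig(n_trials=1, trial_duration=0.05,
                              dbs_window=(0.01, 0.02), seed=2)
        truth = generate_vm_and_spikes(cfg)
        bad = np.full((truth.true_vm.size, 2), 0.5)
        with pytest.raises(ValueError, match="integer"):
            render_movie(truth, cfg, shape=(64, 64), shifts=bad)

    def test_oversized_shifts_rejected(self):
        cfg = GeneratorConfig(n_trials=1, trial_duration=0.05,
                              dbs_window=(0.01, 0.02), seed=2)
        truth = generate_vm_and_spikes(cfg)
        bad = np.zeros((truth.true_vm.size, 2), dtype=int)
        bad[0] = (40, 0)
        with pytest.raises(ValueError, match="shape/4"):
            render_movie(truth, cfg, shape=(64, 64), shifts=bad)
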