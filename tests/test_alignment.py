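"""Event-triggered averaging, evoked change, onset timing, regression."""

import numpy as np
import pytest
from scipy import stats

import voltstim as vs
from voltstim.alignment import (default_norm_window, depolarization_vs_suppression,
                                event_triggered_average, evoked_change,
                                onset_response_timing, opto_entrainment_power,
                                population_average)
from voltstim.containers import StimProtocol, VmTrace

FS = 828.0


def _kernel(lags):
    # alpha-like bump peaking ~9 ms
    k = np.where(lags > 0.003,
                 np.exp(-(lags - 0.003) / 0.015) - np.exp(-(lags - 0.003) / 0.003), 0.0)
    return k / k.max()


class TestEventTriggeredAverage:
    def _events(self, n_events=30, spacing=0.5, start=1.0):
        return start + spacing * np.arange(n_events)

    def test_identical_kernel_recovered_exactly(self):
        events = self._events()
        n = int((events[-1] + 1) * FS)
        values = np.zeros(n)
        lag_grid = np.arange(int(0.05 * FS)) / FS
        k = _kernel(lag_grid)
        for t in events:
            f0 = int(round(t * FS))
            values[f0:f0 + k.size] += k
        avg = event_triggered_average(values, FS, events, lag_range=(-0.01, 0.049),
                                      norm_window=0.01)
        got = avg.mean[avg.lags >= 0][:k.size]
        assert np.allclose(got, k, atol=1e-9)
        assert avg.n_events == 30

    def test_constant_signal_averages_to_zero(self):
        events = self._events()
        n = int((events[-1] + 1) * FS)
        avg = event_triggered_average(np.full(n, 3.3), FS, events,
                                      lag_range=(-0.01, 0.04), norm_window=0.01)
        assert np.allclose(avg.mean, 0.0)

    def test_noise_suppression_scales_with_event_count(self, rng):
        sigma = 1.0
        events = self._events(n_events=64)
        n = int((events[-1] + 1) * FS)
        lag_grid = np.arange(int(0.05 * FS)) / FS
        k = _kernel(lag_grid)
        values = rng.normal(0, sigma, n)
        for t in events:
            f0 = int(round(t * FS))
            values[f0:f0 + k.size] += k
        avg = event_triggered_average(values, FS, events, lag_range=(0.0, 0.049),
                                      norm_window=0.01)
        rms = np.sqrt(np.mean((avg.mean[:k.size] - k) ** 2))
        # averaging-variance oracle: residual RMS ~ sigma/sqrt(E)
        assert rms <= 2 * sigma / np.sqrt(64)

    def test_linearity_of_averaging(self, rng):
        events = self._events(10)
        n = int((events[-1] + 1) * FS)
        x = rng.normal(size=n)
        a1 = event_triggered_average(x, FS, events, (-0.01, 0.03), 0.01)
        a2 = event_triggered_average(3 * x + 7, FS, events, (-0.01, 0.03), 0.01)
        assert np.allclose(a2.mean, 3 * a1.mean, atol=1e-10)

    def test_events_near_edges_dropped_and_counted(self):
        values = np.zeros(int(2 * FS))
        with pytest.warns(UserWarning, match="dropped"):
            avg = event_triggered_average(values, FS, np.array([0.001, 1.0, 1.9999]),
                                          lag_range=(-0.01, 0.05), norm_window=0.01)
        assert avg.n_events == 1 and avg.n_dropped == 2

    def test_trial_boundary_crossing_dropped(self):
        values = np.zeros(int(2 * FS))
        edges = np.array([0, int(FS)])
        with pytest.warns(UserWarning, match="dropped"):
            avg = event_triggered_average(values, FS, np.array([0.5, 0.999]),
                                          lag_range=(-0.01, 0.05),
                                          norm_window=0.01, trial_edges=edges)
        assert avg.n_events == 1

    def test_population_average_sem(self):
        base = event_triggered_average(np.zeros(int(2 * FS)), FS, np.array([1.0]),
                                       (-0.01, 0.03), 0.01)
        a = population_average([base, base, base])
        assert np.allclose(a.mean, 0.0) and np.allclose(a.sem, 0.0)


class TestEvokedChange:
    def test_flat_average_zero(self):
        avg = event_triggered_average(np.zeros(int(2 * FS)), FS, np.array([1.0]),
                                      (-0.01, 0.03), 0.01)
        assert evoked_change(avg) == 0.0

    def test_peak_minus_trough(self):
        events = np.array([1.0])
        n = int(2 * FS)
        values = np.zeros(n)
        f0 = int(FS)
        values[f0 + 5] = 0.2
        avg = event_triggered_average(values, FS, events, (-0.005, 0.025), 0.005)
        assert evoked_change(avg, (0.0, 0.025)) == pytest.approx(0.2)

    def test_norm_window_defaults(self):
        assert default_norm_window(40.0) == pytest.approx(0.010)
        assert default_norm_window(140.0) == pytest.approx(0.005)
        assert default_norm_window(opto=True) == pytest.approx(0.050)


class TestOnsetTiming:
    def test_noiseless_step_detected_at_its_lag(self):
        lags = np.arange(-20, 40) / FS
        sig = np.where(lags >= 10 / FS, 5.0, 0.0)
        trials = np.tile(sig, (6, 1)) + 1e-6 * np.random.default_rng(0).normal(
            size=(6, lags.size))
        out = onset_response_timing(trials, lags, baseline_mask=lags < 0)
        assert out["first_significant_ttest"] == pytest.approx(10 / FS, abs=1e-9)
        assert out["first_crossing_sd"] == pytest.approx(10 / FS, abs=1e-9)

    def test_flat_signal_no_crossing(self):
        lags = np.arange(-20, 40) / FS
        trials = np.zeros((5, lags.size))
        out = onset_response_timing(trials, lags, baseline_mask=lags < 0)
        assert out["first_significant_ttest"] is None
        assert out["first_crossing_sd"] is None

    def test_generator_kernel_peak_lag_recovered(self):
        """First-pulse-aligned Vm peaks within ±2 frames of the kernel's
        9 ms time-to-peak (ground truth from the generator)."""
        cfg = vs.dbs_scenario(40.0, n_trials=8, target_sbr=8.0, seed=6,
                              spike_mode="poisson")
        prot = vs.generate_protocol(cfg)
        truth = vs.generate_vm_and_spikes(cfg, prot)
        det = vs.detrend_trace(vs.render_trace(truth, cfg, prot), prot)
        spikes = vs.detect_spikes(det)
        vm = vs.baseline_normalize(
            vs.normalize_vm(vs.remove_spikes(det, spikes), spikes.mean_amplitude()),
            prot)
        lag_lo, lag_hi = -0.05, 0.02
        lags = np.arange(int(lag_lo * FS), int(lag_hi * FS) + 1) / FS
        snips = []
        for t0 in prot.trial_starts():
            f0 = int(round((t0 + prot.dbs_window[0]) * FS))
            snips.append(vm.values[f0 + int(lag_lo * FS):f0 + int(lag_hi * FS) + 1])
        out = onset_response_timing(np.asarray(snips), lags,
                                    baseline_mask=lags < 0)
        assert out["peak_lag"] == pytest.approx(cfg.dbs_kernel.peak_time(),
                                                abs=2.5 / FS)


class TestOptoPower:
    def _protocol(self):
        return StimProtocol(n_trials=2, trial_duration=3.0, dbs_window=(1.0, 2.0),
                            dbs_frequency=40.0,
                            dbs_pulse_times=1.0 + np.arange(40) / 40.0,
                            opto_onsets=np.arange(24) / 8.0,
                            opto_pulse_width=0.042, opto_frequency=8.0)

    def test_stationary_8hz_sinusoid_zero_change(self):
        prot = self._protocol()
        t = np.arange(int(6 * FS)) / FS
        vm = VmTrace(values=np.sin(2 * np.pi * 8 * t), sampling_rate=FS)
        out = opto_entrainment_power(vm, prot)
        assert out["stim_change"] == pytest.approx(0.0, abs=0.05 * out["baseline"])

    def test_halved_amplitude_quarters_power(self):
        # quadratic power scaling; the 5-cycle wavelet's ~0.1 s temporal
        # support leaks edge power into the windows, so the full-window
        # ratio sits above 0.25 while the window interiors hit it exactly
        prot = self._protocol()
        t = np.arange(int(6 * FS)) / FS
        amp = np.ones_like(t)
        for t0 in prot.trial_starts():
            amp[(t >= t0 + 1.0) & (t < t0 + 2.0)] = 0.5
        vm = VmTrace(values=amp * np.sin(2 * np.pi * 8 * t), sampling_rate=FS)
        out = opto_entrainment_power(vm, prot)
        assert 0.25 <= out["stim_ratio"] <= 0.40
        from voltstim.spectral import morlet_power
        power = morlet_power(vm, np.array([8.0])).power[0]
        f0 = int(round((prot.trial_starts()[0] + 1.25) * FS))
        f1 = int(round((prot.trial_starts()[0] + 1.75) * FS))
        b0 = int(round((prot.trial_starts()[0] + 0.25) * FS))
        b1 = int(round((prot.trial_starts()[0] + 0.75) * FS))
        assert power[f0:f1].mean() / power[b0:b1].mean() == pytest.approx(0.25, rel=0.05)

    def test_saturating_generator_suppresses_stim_power(self):
        cfg = vs.opto_dbs_scenario(40.0, n_trials=6, seed=14)
        prot = vs.generate_protocol(cfg)
        truth = vs.generate_vm_and_spikes(cfg, prot)
        det = vs.detrend_trace(vs.render_trace(truth, cfg, prot), prot)
        spikes = vs.detect_spikes(det)
        vm = vs.normalize_vm(vs.remove_spikes(det, spikes), spikes.mean_amplitude())
        out = opto_entrainment_power(vm, prot)
        assert out["stim_change"] < 0


class TestRegression:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 1, 10)
        fit = depolarization_vs_suppression(x, -2 * x)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_degenerate_regressor_absent(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert depolarization_vs_suppression(np.ones(10),
                                                 np.arange(10.0)) is None

    def test_too_few_neurons_absent(self):
        with pytest.warns(UserWarning, match="3 neurons"):
            assert depolarization_vs_suppression(np.array([1.0, 2.0]),
                                                 np.array([0.0, 1.0])) is None

    def test_null_slope_pvalues_uniform(self, rng):
        """Independent x and y: slope p-values behave as a U(0,1) sample."""
        pvals = []
        for _ in range(200):
            fit = depolarization_vs_suppression(rng.normal(size=30),
                                                rng.normal(size=30))
            pvals.append(fit.p_value)
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 <= frac <= 0.10
        assert stats.kstest(pvals, "uniform").pvalue > 0.001
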