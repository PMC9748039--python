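"""End-to-end orchestration: simulate/load → preprocess → detect → analyze.

A run analyzes a cohort of neurons (each a trial-structured recording),
producing tidy per-neuron tables: spike counts and SBR, window statistics of
baseline-normalized Vm and firing rate, stimulation-frequency entrainment
(band power change and spike-Vm PLV), theta-band PLV, and — for
optogenetics trials — 8 Hz power and PLV before/during/after stimulation.
Every stochastic step derives its seed from the root seed, so a fixed
configuration reproduces byte-identical tables; stage outputs are cached on
disk keyed by a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._version import __version__
from .containers import FluorescenceTrace, StimProtocol
from .preprocess import detrend_trace
from .spectral import (MIN_SPIKES_SINGLE_NEURON, band_averaged_plv,
                       bandpass_phase, plv, spike_phases,
                       stim_band_power_change)
from .spikes import compute_sbr, detect_spikes
from .synthetic import (GeneratorConfig, generate_protocol,
                        generate_vm_and_spikes, render_trace)
from .vm import (baseline_normalize, firing_rate, normalize_vm, remove_spikes,
                 window_stats)
from .alignment import opto_entrainment_power

__all__ = ["RunConfig", "RunReport", "run_pipeline", "analyze_trace",
           "compare_conditions"]

THETA_GRID = np.array([4.0, 6.0, 8.0, 10.0, 12.0])


@dataclass
class RunConfig:
    generator: GeneratorConfig
    n_neurons: int = 5
    seed: int = 0
    k_sd: float = 4.0
    rate_smoothing: float = 0.025
    out_dir: Optional[str] = None

    def config_hash(self) -> str:
        payload = {"generator": self.generator.to_dict(),
                   "n_neurons": self.n_neurons, "seed": self.seed,
                   "k_sd": self.k_sd, "rate_smoothing": self.rate_smoothing,
                   "version": __version__}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {"generator": self.generator.to_dict(),
                "n_neurons": self.n_neurons, "seed": self.seed,
                "k_sd": self.k_sd, "rate_smoothing": self.rate_smoothing}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["generator"] = GeneratorConfig.from_dict(d["generator"])
        d.pop("out_dir", None)
        return cls(**d)


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame]
    provenance: dict
    warnings: list[str] = field(default_factory=list)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump({"provenance": self.provenance,
                       "warnings": self.warnings,
                       "tables": sorted(self.tables)}, fh, indent=1)

    @classmethod
    def load(cls, out_dir) -> "RunReport":
        out = Path(out_dir)
        with open(out / "provenance.json") as fh:
            meta = json.load(fh)
        tables = {name: pd.read_csv(out / f"{name}.csv")
                  for name in meta["tables"]}
        return cls(tables=tables, provenance=meta["provenance"],
                   warnings=meta.get("warnings", []))


def _window_frame_ranges(protocol: StimProtocol, fs: float, kind: str,
                         n_frames: int) -> list[tuple[int, int]]:
    """Per-trial frame windows: 'baseline' (1 s pre-onset), 'stim', 'post'."""
    out = []
    for t0 in protocol.trial_starts():
        onset = int(round((t0 + protocol.dbs_window[0]) * fs))
        offset = int(round((t0 + protocol.dbs_window[1]) * fs))
        trial_end = int(round((t0 + protocol.trial_duration) * fs))
        if kind == "baseline":
            rng = (max(int(round(t0 * fs)), onset - int(round(fs))), onset)
        elif kind == "stim":
            rng = (onset, offset)
        elif kind == "post":
            rng = (offset, min(offset + int(round(fs)), trial_end))
        else:
            raise ValueError(kind)
        rng = (rng[0], min(rng[1], n_frames))
        if rng[1] > rng[0]:
            out.append(rng)
    return out


def _windowed_plv(phase_series: np.ndarray, spikes, windows) -> tuple[float, int]:
    phases = np.concatenate([
        spike_phases(phase_series, spikes, window=w).phases for w in windows
    ]) if windows else np.empty(0)
    if phases.size == 0:
        return float("nan"), 0
    return float(np.abs(np.mean(np.exp(1j * phases)))), int(phases.size)


def analyze_trace(trace: FluorescenceTrace, protocol: StimProtocol,
                  k_sd: float = 4.0, rate_smoothing: float = 0.025) -> dict:
    """Full single-neuron analysis of one (raw) fluorescence trace."""
    fs = trace.sampling_rate
    detrended = detrend_trace(trace, protocol)
    spikes = detect_spikes(detrended, k_sd=k_sd)
    sbr = compute_sbr(detrended, spikes) if spikes.n_spikes else None
    removed = remove_spikes(detrended, spikes)
    mean_amp = spikes.mean_amplitude() if spikes.n_spikes else None
    vm = normalize_vm(removed, mean_amp)
    vm_norm = baseline_normalize(vm, protocol)
    rate = firing_rate(spikes, trace.n_frames, fs,
                       smoothing_window=rate_smoothing,
                       trial_boundaries=trace.trial_boundaries)

    result = {
        "spikes": spikes, "sbr": sbr, "vm": vm, "vm_norm": vm_norm,
        "rate": rate,
        "vm_stats": window_stats(vm_norm, protocol),
        "rate_stats": window_stats(rate, protocol),
    }

    n = trace.n_frames
    stim_windows = _window_frame_ranges(protocol, fs, "stim", n)
    base_windows = _window_frame_ranges(protocol, fs, "baseline", n)
    post_windows = _window_frame_ranges(protocol, fs, "post", n)

    f_stim = protocol.dbs_frequency
    result["stim_power"] = stim_band_power_change(vm, protocol, f_stim)
    phase_stim = bandpass_phase(vm, f_stim)
    result["plv_stim_freq"] = dict(zip(
        ("baseline", "stim", "post"),
        (_windowed_plv(phase_stim, spikes, w)
         for w in (base_windows, stim_windows, post_windows))))

    theta_base, theta_stim = [], []
    for f in THETA_GRID:
        phase = bandpass_phase(vm, f)
        theta_base.append(_windowed_plv(phase, spikes, base_windows)[0])
        theta_stim.append(_windowed_plv(phase, spikes, stim_windows)[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result["theta_plv"] = {
            "baseline": band_averaged_plv(THETA_GRID, np.asarray(theta_base)),
            "stim": band_averaged_plv(THETA_GRID, np.asarray(theta_stim)),
        }

    if protocol.opto_onsets.size:
        result["opto_power"] = opto_entrainment_power(
            vm, protocol, opto_frequency=protocol.opto_frequency or 8.0)
        phase8 = bandpass_phase(vm, protocol.opto_frequency or 8.0)
        result["plv_opto_freq"] = dict(zip(
            ("baseline", "stim", "post"),
            (_windowed_plv(phase8, spikes, w)
             for w in (base_windows, stim_windows, post_windows))))
    return result


def run_pipeline(config: RunConfig, use_cache: bool = True) -> RunReport:
    """Simulate and analyze a cohort of neurons; return tidy tables.

    Neuron ``i`` uses generator seed ``seed + i`` (kept below 2^31). Results
    are cached under ``out_dir/report_<hash>`` and reused when the
    configuration hash matches.
    """
    cache_dir = None
    if config.out_dir is not None:
        cache_dir = Path(config.out_dir) / f"report_{config.config_hash()}"
        if use_cache and (cache_dir / "provenance.json").exists():
            return RunReport.load(cache_dir)

    caught: list[str] = []
    rows_neuron, rows_windows, rows_entrain, rows_opto = [], [], [], []
    for i in range(config.n_neurons):
        gcfg = GeneratorConfig.from_dict(config.generator.to_dict())
        gcfg.seed = int((config.seed + i) % (2 ** 31))
        protocol = generate_protocol(gcfg)
        truth = generate_vm_and_spikes(gcfg, protocol)
        trace = render_trace(truth, gcfg, protocol)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            res = analyze_trace(trace, protocol, k_sd=config.k_sd,
                                rate_smoothing=config.rate_smoothing)
        caught.extend(f"neuron {i}: {w.message}" for w in wlist)

        sbr = res["sbr"]
        rows_neuron.append({
            "neuron": i, "seed": gcfg.seed,
            "n_spikes": res["spikes"].n_spikes,
            "n_true_spikes": truth.true_spike_frames.size,
            "sbr": sbr.sbr if sbr else np.nan,
            "mean_spike_amplitude": sbr.mean_spike_amplitude if sbr else np.nan,
        })
        for signal_name in ("vm", "rate"):
            ws = res[f"{signal_name}_stats"]
            rows_windows.append({
                "neuron": i, "signal": signal_name,
                "baseline": ws.baseline, "transient": ws.transient,
                "sustained": ws.sustained, "post": ws.post,
                "transient_change": ws.transient_change,
                "sustained_change": ws.sustained_change,
                "post_change": ws.post_change,
            })
        ent = {"neuron": i,
               "stim_frequency": protocol.dbs_frequency,
               "stim_power_ratio": res["stim_power"]["ratio"],
               "theta_plv_baseline": res["theta_plv"]["baseline"],
               "theta_plv_stim": res["theta_plv"]["stim"]}
        for key, (value, count) in res["plv_stim_freq"].items():
            ent[f"plv_{key}"] = value
            ent[f"n_spikes_{key}"] = count
        rows_entrain.append(ent)
        if "opto_power" in res:
            row = {"neuron": i, **{f"power8_{k}": v
                                   for k, v in res["opto_power"].items()}}
            for key, (value, count) in res["plv_opto_freq"].items():
                row[f"plv8_{key}"] = value
                row[f"n_spikes_{key}"] = count
            vm_ws = res["vm_stats"]
            row["vm_change_stim"] = (vm_ws.transient_change * 0.15
                                     + vm_ws.sustained_change * 0.85)
            rows_opto.append(row)

    tables = {
        "neurons": pd.DataFrame(rows_neuron),
        "window_stats": pd.DataFrame(rows_windows),
        "entrainment": pd.DataFrame(rows_entrain),
    }
    if rows_opto:
        tables["opto"] = pd.DataFrame(rows_opto)
    report = RunReport(
        tables=tables,
        provenance={"config": config.to_dict(),
                    "config_hash": config.config_hash(),
                    "version": __version__},
        warnings=sorted(set(caught)),
    )
    if cache_dir is not None:
        report.save(cache_dir)
    return report


def _extract(report_or_values, statistic: Optional[str]):
    if isinstance(report_or_values, RunReport):
        table, column = statistic.split(".", 1)
        return report_or_values.tables[table][column].to_numpy(float)
    return np.asarray(report_or_values, dtype=float)


def compare_conditions(a, b, statistic: Optional[str] = None,
                       paired: bool = True, method: str = "ttest",
                       n_permutations: int = 1000, seed: int = 0) -> Optional[dict]:
    """Two-sided comparison of a per-neuron statistic between conditions.

    ``a``/``b`` are arrays or :class:`RunReport` objects (with ``statistic``
    like ``"window_stats.transient_change"``). Paired comparisons use the
    paired t (df = n − 1); independent use the two-sample t. For PLV-like
    bounded statistics, ``method="permutation"`` exchanges condition labels.
    """
    x, y = _extract(a, statistic), _extract(b, statistic)
    ok = np.isfinite(x) & np.isfinite(y) if paired else None
    if paired:
        x, y = x[ok], y[ok]
        n = x.size
    else:
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        n = min(x.size, y.size)
    if n < 3:
        warnings.warn("comparison needs n ≥ 3 per condition")
        return None
    if method == "ttest":
        if paired and np.allclose(x - y, (x - y)[0]):
            # zero-variance differences: identical samples -> no effect
            d0 = float((x - y)[0])
            t_stat = 0.0 if d0 == 0 else np.inf * np.sign(d0)
            return {"t": t_stat, "df": int(x.size - 1),
                    "p": 1.0 if d0 == 0 else 0.0, "paired": True, "n": int(n)}
        if paired:
            res = stats.ttest_rel(x, y)
            df = x.size - 1
        else:
            res = stats.ttest_ind(x, y)
            df = x.size + y.size - 2
        return {"t": float(res.statistic), "df": int(df),
                "p": float(res.pvalue), "paired": paired, "n": int(n)}
    if method == "permutation":
        rng = np.random.default_rng(seed)
        if paired:
            diffs = x - y
            obs = abs(diffs.mean())
            signs = rng.choice([-1.0, 1.0], size=(n_permutations, diffs.size))
            null = np.abs((signs * diffs).mean(axis=1))
        else:
            pooled = np.concatenate([x, y])
            obs = abs(x.mean() - y.mean())
            null = np.empty(n_permutations)
            for i in range(n_permutations):
                perm = rng.permutation(pooled)
                null[i] = abs(perm[:x.size].mean() - perm[x.size:].mean())
        p = (1.0 + np.sum(null >= obs)) / (1.0 + n_permutations)
        return {"statistic": float(obs), "p": float(p),
                "paired": paired, "n": int(n), "method": "permutation"}
    raise ValueError(f"unknown method {method!r}")
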