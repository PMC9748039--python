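"""Readers and writers for the pipeline's on-disk formats.

Movies are multi-page TIFF; traces, spikes and shifts are CSV; protocols
and run configuration are YAML/JSON; ground truth travels as a JSON sidecar.
Masks load from PNG (nonzero = inside) or run-length JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import (FluorescenceTrace, RoiMask, ShiftSeries, SpikeTrain,
                         StimProtocol, VoltageMovie)
from .synthetic import GeneratorConfig, GroundTruth

__all__ = [
    "read_movie", "write_movie", "read_mask", "write_mask_rle",
    "read_trace_csv", "write_trace_csv", "write_spikes_csv", "read_spikes_csv",
    "write_shifts_csv", "read_shifts_csv", "read_protocol", "write_protocol",
    "write_ground_truth", "read_ground_truth", "read_generator_config",
]


def read_movie(path, sampling_rate: float = 828.0,
               trial_boundaries=None) -> VoltageMovie:
    frames = tifffile.imread(str(path)).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    if trial_boundaries is None:
        trial_boundaries = np.zeros(1, dtype=int)
    return VoltageMovie(frames=frames, sampling_rate=sampling_rate,
                        trial_boundaries=np.asarray(trial_boundaries, dtype=int))


def write_movie(path, movie: VoltageMovie) -> None:
    tifffile.imwrite(str(path), movie.frames.astype(np.float32))


def read_mask(path, label: str = "neuron") -> RoiMask:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            spec = json.load(fh)
        mask = np.zeros(tuple(spec["shape"]), dtype=bool)
        for row, start, length in spec["runs"]:
            mask[row, start:start + length] = True
        return RoiMask(mask=mask, label=spec.get("label", label))
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return RoiMask(mask=img > 0, label=label)


def write_mask_rle(path, mask: RoiMask) -> None:
    runs = []
    for row in range(mask.mask.shape[0]):
        line = mask.mask[row]
        idx = np.flatnonzero(np.diff(np.concatenate([[0], line.view(np.int8), [0]])))
        for start, stop in zip(idx[::2], idx[1::2]):
            runs.append([int(row), int(start), int(stop - start)])
    with open(path, "w") as fh:
        json.dump({"shape": list(mask.mask.shape), "label": mask.label,
                   "runs": runs}, fh)


def write_trace_csv(path, trace: FluorescenceTrace, column: str = "fluorescence") -> None:
    pd.DataFrame({"frame": np.arange(trace.n_frames),
                  column: trace.values}).to_csv(path, index=False)


def read_trace_csv(path, sampling_rate: float = 828.0,
                   trial_boundaries=None, protocol=None) -> FluorescenceTrace:
    df = pd.read_csv(path)
    col = [c for c in df.columns if c != "frame"][0]
    if trial_boundaries is None:
        trial_boundaries = (protocol.trial_boundaries(sampling_rate)
                            if protocol is not None else np.zeros(1, dtype=int))
    return FluorescenceTrace(values=df[col].to_numpy(), sampling_rate=sampling_rate,
                             trial_boundaries=np.asarray(trial_boundaries, dtype=int),
                             protocol=protocol)


def write_spikes_csv(path, spikes: SpikeTrain, sampling_rate: float) -> None:
    pd.DataFrame({"frame": spikes.spike_frames,
                  "time_s": spikes.spike_frames / sampling_rate,
                  "amplitude": spikes.spike_amplitudes}).to_csv(path, index=False)


def read_spikes_csv(path) -> SpikeTrain:
    df = pd.read_csv(path)
    return SpikeTrain(spike_frames=df["frame"].to_numpy(int),
                      spike_amplitudes=df["amplitude"].to_numpy(float),
                      threshold_used=float("nan"), baseline_sd=float("nan"))


def write_shifts_csv(path, shifts: ShiftSeries) -> None:
    pd.DataFrame({"frame": np.arange(len(shifts)),
                  "dy": shifts.shifts[:, 0],
                  "dx": shifts.shifts[:, 1]}).to_csv(path, index=False)


def read_shifts_csv(path) -> ShiftSeries:
    df = pd.read_csv(path)
    return ShiftSeries(shifts=df[["dy", "dx"]].to_numpy(float))


def _load_structured(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def read_protocol(path) -> StimProtocol:
    return StimProtocol.from_dict(_load_structured(path))


def write_protocol(path, protocol: StimProtocol) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            yaml.safe_dump(protocol.to_dict(), fh)
        else:
            json.dump(protocol.to_dict(), fh, indent=1)


def read_generator_config(path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(_load_structured(path))


def write_ground_truth(path, truth: GroundTruth, protocol: StimProtocol,
                       seed: int) -> None:
    payload = {
        "seed": seed,
        "protocol": protocol.to_dict(),
        "true_spike_frames": truth.true_spike_frames.tolist(),
        "true_spike_amplitude": truth.true_spike_amplitude,
        "true_shifts": (truth.true_shifts.tolist()
                        if truth.true_shifts is not None else None),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
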