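"""Rigid motion correction and ROI trace extraction.

Trials are concatenated before correction; each frame's displacement is the
integer (optionally subpixel-refined) shift maximizing the cross-correlation
with a reference image (default: the mean frame of the concatenated
recording). Correlation is computed spectrally with explicit zero-padding so
large shifts do not alias around the frame, and the search is capped at a
configurable radius.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
from numpy.fft import irfft2, rfft2

from .containers import FluorescenceTrace, RoiMask, ShiftSeries, VoltageMovie

__all__ = ["estimate_shifts", "apply_shifts", "extract_roi_trace"]


def _reference_image(movie: VoltageMovie, reference: Union[str, np.ndarray]) -> np.ndarray:
    if isinstance(reference, np.ndarray):
        return np.asarray(reference, dtype=float)
    if reference == "mean":
        return movie.frames.mean(axis=0)
    if reference == "first":
        return movie.frames[0].astype(float)
    raise ValueError(f"unknown reference {reference!r}")


def _parabolic_refine(cc: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Subpixel peak via separable 3-point parabola around the integer peak."""
    dy, dx = 0.0, 0.0
    py, px = peak
    if 0 < py < cc.shape[0] - 1:
        c0, c1, c2 = cc[py - 1, px], cc[py, px], cc[py + 1, px]
        denom = c0 - 2 * c1 + c2
        if denom < 0:
            dy = 0.5 * (c0 - c2) / denom
    if 0 < px < cc.shape[1] - 1:
        c0, c1, c2 = cc[py, px - 1], cc[py, px], cc[py, px + 1]
        denom = c0 - 2 * c1 + c2
        if denom < 0:
            dx = 0.5 * (c0 - c2) / denom
    return dy, dx


def estimate_shifts(movie: VoltageMovie,
                    reference: Union[str, np.ndarray] = "mean",
                    search_radius: int = 20,
                    subpixel: bool = False) -> ShiftSeries:
    """Estimate per-frame rigid displacements relative to a reference image.

    Returns, for each frame, the displacement ``(dy, dx)`` maximizing the
    zero-padded cross-correlation with the reference (both images
    mean-subtracted), restricted to ``|shift| ≤ search_radius``. With
    ``subpixel=True``, the correlation peak is refined by parabolic
    interpolation; otherwise shifts are integer pixels.
    """
    if movie.n_frames < 1:
        raise ValueError("movie must contain at least one frame")
    ref = _reference_image(movie, reference)
    ref = ref - ref.mean()
    ny, nx = movie.frame_shape
    py, px = 2 * ny, 2 * nx  # zero-padding: no circular wraparound of shifts < N
    f_ref = rfft2(ref, s=(py, px))

    # lag indices allowed by the search radius, in FFT (wrapped) coordinates
    lag_y = np.fft.fftfreq(py, 1.0 / py).astype(int)
    lag_x = np.fft.fftfreq(px, 1.0 / px).astype(int)
    sel_y = np.abs(lag_y) <= search_radius
    sel_x = np.abs(lag_x) <= search_radius

    shifts = np.zeros((movie.n_frames, 2))
    for i in range(movie.n_frames):
        frame = movie.frames[i]
        if np.ptp(frame) == 0:
            warnings.warn(f"frame {i} is constant; correlation undefined, shift set to (0, 0)")
            continue
        img = frame - frame.mean()
        cc = irfft2(rfft2(img, s=(py, px)) * np.conj(f_ref), s=(py, px))
        sub = cc[np.ix_(sel_y, sel_x)]
        peak_flat = int(np.argmax(sub))
        iy, ix = np.unravel_index(peak_flat, sub.shape)
        dy = float(lag_y[sel_y][iy])
        dx = float(lag_x[sel_x][ix])
        if subpixel:
            ry, rx = _parabolic_refine(sub, (iy, ix))
            dy, dx = dy + ry, dx + rx
        shifts[i] = (dy, dx)
    ref_name = reference if isinstance(reference, str) else "array"
    return ShiftSeries(shifts=shifts, reference=ref_name)


def _translate_frame(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.roll(np.roll(frame, dy, axis=0), dx, axis=1)
    if dy > 0:
        out[:dy, :] = fill
    elif dy < 0:
        out[dy:, :] = fill
    if dx > 0:
        out[:, :dx] = fill
    elif dx < 0:
        out[:, dx:] = fill
    return out


def apply_shifts(movie: VoltageMovie, shifts: ShiftSeries) -> VoltageMovie:
    """Translate each frame by the negated estimated shift (rigid correction).

    Out-of-frame pixels are filled with the frame median. For integer shifts
    the interior pixels round-trip exactly (shift then unshift is identity
    away from the filled border).
    """
    if len(shifts) != movie.n_frames:
        raise ValueError("shift series length must match frame count")
    s = np.round(shifts.shifts).astype(int)
    out = np.empty_like(movie.frames)
    for i in range(movie.n_frames):
        fill = float(np.median(movie.frames[i]))
        out[i] = _translate_frame(movie.frames[i], -s[i, 0], -s[i, 1], fill)
    return VoltageMovie(frames=out, sampling_rate=movie.sampling_rate,
                        trial_boundaries=movie.trial_boundaries)


def extract_roi_trace(movie: VoltageMovie, mask: RoiMask,
                      protocol=None) -> FluorescenceTrace:
    """Per-frame unweighted mean of the pixels inside the ROI mask."""
    if mask.mask.shape != movie.frame_shape:
        raise ValueError("mask shape must match the movie frames")
    values = movie.frames[:, mask.mask].mean(axis=1)
    return FluorescenceTrace(values=values, sampling_rate=movie.sampling_rate,
                             trial_boundaries=movie.trial_boundaries,
                             protocol=protocol)
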