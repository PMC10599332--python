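"""Projection-domain corrections applied before phase retrieval and FBP.

Order of operations in the standard pipeline: flat/dark normalization,
hot-pixel repair, rotation-axis correction, then (after sinogram
assembly) wavelet-FFT ring filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage, signal

from .simulate import AcquisitionGeometry, HologramStack

__all__ = [
    "NormalizedStack",
    "flat_dark_correct",
    "repair_hot_pixels",
    "find_rotation_axis",
    "apply_axis_shift",
    "ring_filter_waveletfft",
    "ring_metric",
]

#: smallest admissible normalized intensity / denominator value
_FLOOR = 1e-6


@dataclass
class NormalizedStack:
    """Flat/dark-corrected frames (background ~1) with a correction log."""

    frames: np.ndarray  # (n_angles, nz, nx)
    geometry: AcquisitionGeometry
    correction_log: list[dict] = field(default_factory=list)

    def log(self, step: str, **params) -> None:
        self.correction_log.append({"step": step, **params})


def flat_dark_correct(stack: HologramStack) -> NormalizedStack:
    """I_norm = (I - <darks>) / (<flats> - <darks>), floored at a small
    positive value.

    Because the static column-gain pattern is shared between frames and
    flats, the division removes it.
    """
    if len(stack.flats) < 1 or len(stack.darks) < 1:
        raise ValueError("need at least one flat and one dark frame")
    dark = stack.darks.mean(axis=0)
    flat = stack.flats.mean(axis=0)
    denom = flat - dark
    if np.any(denom < _FLOOR):
        raise ValueError("flat field not distinguishable from dark field")
    frames = np.clip((stack.frames - dark[None]) / denom[None], _FLOOR, None)
    out = NormalizedStack(frames, stack.geometry)
    out.log("flat_dark_correct", n_flats=len(stack.flats), n_darks=len(stack.darks))
    return out


def repair_hot_pixels(frame: np.ndarray, k_mad: float = 10.0) -> tuple[np.ndarray, int]:
    """Replace outlier pixels by the mean of their 8-neighbourhood.

    A pixel is an outlier when it deviates from its 3x3 neighbourhood
    median by more than ``k_mad`` times the global median absolute
    deviation of that residual.  Returns (repaired frame, count).
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    frame = np.asarray(frame, dtype=np.float64)
    med = ndimage.median_filter(frame, size=3, mode="nearest")
    resid = frame - med
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad == 0:
        # no noise floor (majority of residuals exactly zero): flag only
        # extreme isolated deviations
        if not np.any(resid):
            return frame.copy(), 0
        mask = np.abs(resid) > 0.5 * np.abs(resid).max()
    else:
        mask = np.abs(resid) > k_mad * mad
    if not mask.any():
        return frame.copy(), 0
    # mean of valid (non-hot) 8-neighbours
    valid = (~mask).astype(np.float64)
    kernel = np.ones((3, 3)); kernel[1, 1] = 0.0
    neigh_sum = ndimage.convolve(frame * valid, kernel, mode="nearest")
    neigh_cnt = ndimage.convolve(valid, kernel, mode="nearest")
    repaired = frame.copy()
    fillable = mask & (neigh_cnt > 0)
    repaired[fillable] = neigh_sum[fillable] / neigh_cnt[fillable]
    return repaired, int(mask.sum())


def repair_stack(frames: np.ndarray, k_mad: float = 10.0) -> tuple[np.ndarray, int]:
    """Hot-pixel repair applied frame-by-frame; returns total count."""
    out = np.empty_like(frames)
    total = 0
    for i, f in enumerate(frames):
        out[i], n = repair_hot_pixels(f, k_mad)
        total += n
    return out, total


def _xcorr_shift(a: np.ndarray, b: np.ndarray, upsample: int = 16) -> float:
    """Sub-pixel lag maximising the cross-correlation of two 1D signals.

    The correlation is band-limited-upsampled by zero-padding its
    spectrum, then the peak refined by parabolic interpolation.  Inputs
    must be baseline-free: a constant pedestal, zero-padded, correlates
    like a box and drags the peak toward zero lag.
    """
    n = len(a)
    spec = np.fft.rfft(a, 2 * n) * np.conj(np.fft.rfft(b, 2 * n))
    m = 2 * n * upsample
    corr = np.fft.irfft(spec, m)
    corr = np.roll(corr, m // 2)  # lags -n .. n in steps of 1/upsample
    k = int(np.argmax(corr))
    if 0 < k < m - 1:
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        denom = y0 - 2 * y1 + y2
        frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        frac = 0.0
    return ((k + frac) - m // 2) / upsample


def find_rotation_axis(stack: NormalizedStack, angle_tol: float = 1.0,
                       n_pairs: int = 8) -> float:
    """Signed horizontal offset of the rotation axis from the detector
    center column, from mirrored projection pairs 180 degrees apart.

    A projection at theta and the horizontally mirrored projection at
    theta+180 image the same object; their relative displacement is
    twice the axis offset.  Cross-correlation of depth-summed profiles
    with sub-pixel refinement, averaged over up to ``n_pairs`` evenly
    spaced opposing pairs to beat down noise.
    """
    angles = stack.geometry.angles
    span = angles.max() - angles.min()
    if span < 180.0 - angle_tol:
        raise ValueError("stack must cover at least 180 degrees")
    n_ang = len(angles)
    offsets = []
    for i0 in range(0, n_ang, max(1, n_ang // max(n_pairs, 1)))[:n_pairs]:
        target = (angles[i0] + 180.0) % 360.0
        j = int(np.argmin(np.abs((angles - target + 180.0) % 360.0 - 180.0)))
        mismatch = abs((angles[j] - target + 180.0) % 360.0 - 180.0)
        if mismatch > angle_tol:
            continue
        p0 = stack.frames[i0].sum(axis=0)
        p180 = stack.frames[j].sum(axis=0)[::-1]
        # remove the flat background pedestal so the zero-padded
        # correlation is not biased toward zero lag by box edges
        edge = max(3, len(p0) // 20)
        p0 = p0 - np.median(np.r_[p0[:edge], p0[-edge:]])
        p180 = p180 - np.median(np.r_[p180[:edge], p180[-edge:]])
        lag = _xcorr_shift(p0, p180)
        n = len(p0)
        # mirroring about index (n-1)/2 vs axis at c: lag = 2c - (n-1)
        offsets.append((lag + (n - 1) - 2 * (n // 2)) / 2.0)
    if not offsets:
        raise ValueError(f"no opposing projection pairs within {angle_tol} deg")
    return float(np.mean(offsets))


def apply_axis_shift(frames: np.ndarray, offset: float) -> np.ndarray:
    """Resample frames so the rotation axis lands on the detector center
    column (shift by -offset along the last axis, linear interpolation)."""
    if offset == 0:
        return frames.copy()
    out = np.empty_like(frames)
    for i, f in enumerate(frames):
        out[i] = ndimage.shift(f, (0.0, -offset), order=1, mode="nearest")
    return out


def ring_filter_waveletfft(
    sinogram: np.ndarray,
    wavelet_name: str = "db25",
    levels: int = 4,
    sigma: float = 2.4,
) -> np.ndarray:
    """Wavelet-FFT stripe suppression on an (angle x detector) sinogram.

    Multilevel DWT along the detector axis; in each detail band the FFT
    along the angle axis is damped by the Gaussian notch
    g(u) = 1 - exp(-u^2/(2*sigma^2)) centered on zero angular frequency,
    removing components constant along angle (the stripes that
    backproject into rings) while leaving genuine structure intact.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    sino = np.asarray(sinogram, dtype=np.float64)
    if sino.ndim != 2:
        raise ValueError("sinogram must be 2D (angle x detector)")
    if sino.shape[1] < 2**levels:
        raise ValueError("detector width too small for the requested levels")
    if wavelet_name not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {wavelet_name!r}")
    coeffs = pywt.wavedec(sino, wavelet_name, level=levels, axis=1, mode="symmetric")
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        spec = np.fft.fft(detail, axis=0)
        u = np.fft.fftfreq(detail.shape[0]) * detail.shape[0]
        notch = 1.0 - np.exp(-(u**2) / (2.0 * sigma**2))
        spec *= notch[:, None]
        out.append(np.real(np.fft.ifft(spec, axis=0)))
    filtered = pywt.waverec(out, wavelet_name, axis=1, mode="symmetric")
    return filtered[:, : sino.shape[1]]


def ring_metric(sinogram: np.ndarray) -> float:
    """Stripe-severity score: std of the high-pass-filtered angular mean
    per detector column.  Strictly decreases when rings are removed."""
    col_mean = np.asarray(sinogram, dtype=np.float64).mean(axis=0)
    smooth = ndimage.gaussian_filter1d(col_mean, 5.0, mode="nearest")
    return float(np.std(col_mean - smooth))
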