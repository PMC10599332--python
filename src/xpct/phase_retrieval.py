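"""Single-distance phase retrieval for inline holograms.

Two linear single-step methods are provided, both written in reduced
frequency units nu (cycles/pixel) with the phase-contrast transfer
argument chi(nu) = pi*|nu|^2/F:

* CTF: inversion of the weak-object transfer model
  I_hat = 2*(sin chi + (beta/delta)*cos chi) * phi_hat, with two-band
  Tikhonov regularization (one weight below the first |sin chi|
  maximum, one above).
* Paganin: the single-material low-pass filter
  1/(1 + (delta/beta)*pi*|nu|^2/F) applied to the intensity, followed
  by a logarithm.

Both return maps in the same "projected phase" convention,
phi = (2*pi/lambda) * integral(delta) >= 0 for delta > 0 objects, so
either can feed the same tomographic reconstruction path.  The DC
component is not constrained by either filter and is set to zero mean
contrast (documented offset convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "RetrievalConfig",
    "PhaseMap",
    "FresnelEstimate",
    "ctf_retrieve",
    "paganin_retrieve",
    "retrieve",
    "estimate_fresnel_number",
    "radial_power_spectrum",
]


@dataclass(frozen=True)
class RetrievalConfig:
    """Parameters of single-distance retrieval.

    delta_beta is the homogeneous-object coupling ratio; reg_low/reg_high
    are Tikhonov weights below/above the first CTF maximum (CTF method
    only).
    """

    delta_beta: float
    fresnel: float
    reg_low: float = 1e-6
    reg_high: float = 1e-2
    method: str = "ctf"
    pad: bool = True

    def __post_init__(self) -> None:
        if self.delta_beta <= 0:
            raise ValueError("delta_beta must be positive")
        if self.fresnel <= 0:
            raise ValueError("fresnel number must be positive")
        if self.reg_low < 0 or self.reg_high < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.method not in ("ctf", "paganin"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class PhaseMap:
    """Retrieved 2D phase map (radians, projected-phase convention)."""

    values: np.ndarray
    config: RetrievalConfig

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase map must be finite")


def _freq_sq(shape: tuple[int, int]) -> np.ndarray:
    nu_y = np.fft.fftfreq(shape[0])[:, None]
    nu_x = np.fft.fftfreq(shape[1])[None, :]
    return nu_y**2 + nu_x**2


def _pad(img: np.ndarray) -> tuple[np.ndarray, tuple[slice, slice]]:
    ny, nx = img.shape
    py, px = ny // 2, nx // 2
    return (
        np.pad(img, ((py, py), (px, px)), mode="edge"),
        (slice(py, py + ny), slice(px, px + nx)),
    )


def ctf_retrieve(hologram: np.ndarray, config: RetrievalConfig) -> PhaseMap:
    """Linearized CTF inversion of a normalized hologram.

    phi_hat = -FT[I - 1] / (2*(sin chi + cos chi/(delta/beta)) + reg(nu));
    the sign maps the physically negative phase of a delta > 0 object
    onto the positive projected-phase convention.
    """
    if config.method != "ctf":
        raise ValueError("config.method must be 'ctf'")
    holo = np.asarray(hologram, dtype=np.float64)
    contrast = holo - 1.0
    crop = None
    if config.pad:
        contrast, crop = _pad(contrast)
    chi = math.pi * _freq_sq(contrast.shape) / config.fresnel
    denom = 2.0 * (np.sin(chi) + np.cos(chi) / config.delta_beta)
    # band edge: first maximum of |sin chi| at chi = pi/2
    reg = np.where(chi < math.pi / 2.0, config.reg_low, config.reg_high)
    # keep the sign of the transfer function; regularize its magnitude
    filt = denom / (denom**2 + reg)
    spec = np.fft.fft2(contrast) * filt
    spec[0, 0] = 0.0  # DC undefined by the filter; zero-mean convention
    phase = -np.real(np.fft.ifft2(spec))
    if crop is not None:
        phase = phase[crop]
    return PhaseMap(phase, config)


def paganin_retrieve(intensity: np.ndarray, config: RetrievalConfig) -> PhaseMap:
    """Single-material (Paganin) retrieval of a normalized intensity.

    out = (delta_beta/2) * ln( IFT[ FT[I] / (1 + delta_beta*pi*|nu|^2/F) ] ),
    sign-flipped into the projected-phase convention (positive inside an
    absorbing, phase-shifting object), with the mean contrast removed.
    """
    if config.method != "paganin":
        raise ValueError("config.method must be 'paganin'")
    inten = np.asarray(intensity, dtype=np.float64)
    crop = None
    if config.pad:
        inten, crop = _pad(inten)
    filt = 1.0 / (1.0 + config.delta_beta * math.pi * _freq_sq(inten.shape) / config.fresnel)
    smooth = np.real(np.fft.ifft2(np.fft.fft2(inten) * filt))
    floor = 1e-8
    if np.all(smooth <= floor):
        raise ValueError("intensity non-positive everywhere after filtering")
    phase = -0.5 * config.delta_beta * np.log(np.clip(smooth, floor, None))
    if crop is not None:
        phase = phase[crop]
    # zero-mean offset convention, matching the CTF path's suppressed DC
    return PhaseMap(phase - phase.mean(), config)


def retrieve(hologram: np.ndarray, config: RetrievalConfig) -> PhaseMap:
    """Dispatch on ``config.method``."""
    if config.method == "ctf":
        return ctf_retrieve(hologram, config)
    return paganin_retrieve(hologram, config)


def radial_power_spectrum(image: np.ndarray, n_bins: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectrum of (image - mean).

    Returns (nu, psd) with nu in cycles/pixel up to 0.5.
    """
    img = np.asarray(image, dtype=np.float64)
    spec = np.abs(np.fft.fft2(img - img.mean())) ** 2
    nu = np.sqrt(_freq_sq(img.shape))
    if n_bins is None:
        n_bins = min(img.shape) // 2
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    which = np.digitize(nu.ravel(), edges) - 1
    valid = (which >= 0) & (which < n_bins)
    sums = np.bincount(which[valid], weights=spec.ravel()[valid], minlength=n_bins)
    cnts = np.bincount(which[valid], minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    psd = np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)
    return centers, psd


@dataclass
class FresnelEstimate:
    """Result of hologram-based Fresnel-number refinement."""

    fresnel: float
    warning: bool = False
    minima_nu: np.ndarray = field(default_factory=lambda: np.array([]))

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.fresnel


def estimate_fresnel_number(
    hologram: np.ndarray,
    f_initial: float,
    max_rel_dev: float = 0.20,
) -> FresnelEstimate:
    """Refine the Fresnel number from the radially averaged power
    spectrum of a hologram.

    For a phase-dominated object the hologram spectrum carries zeros of
    sin(chi) at nu_m = sqrt(m*F).  Detected minima of the radial PSD are
    matched to the orders m predicted from ``f_initial`` and F is
    re-fitted by least squares (nu_m^2 = m*F).  The result is clamped to
    within ``max_rel_dev`` of the initial value.  If no usable minima
    are found, ``f_initial`` is returned with the warning flag set.
    """
    holo = np.asarray(hologram, dtype=np.float64)
    if np.allclose(holo, holo.flat[0]):
        return FresnelEstimate(f_initial, warning=True)
    nu, psd = radial_power_spectrum(holo)
    good = psd > 0
    if good.sum() < 8:
        return FresnelEstimate(f_initial, warning=True)
    log_psd = np.log(np.clip(psd, psd[good].min() * 1e-3, None))
    smooth = ndimage.gaussian_filter1d(log_psd, 1.5, mode="nearest")
    # envelope-detrended so broad spectral decay does not hide the zeros
    envelope = ndimage.gaussian_filter1d(log_psd, 12.0, mode="nearest")
    dips = smooth - envelope
    min_idx, _ = signal.find_peaks(-dips, prominence=0.15)
    if len(min_idx) == 0:
        return FresnelEstimate(f_initial, warning=True)
    nu_min = nu[min_idx]

    # coarse alignment: scan F over the admissible band and score how well
    # the predicted zeros land in PSD dips (interpolated detrended value)
    lo, hi = f_initial * (1 - max_rel_dev), f_initial * (1 + max_rel_dev)
    f_grid = np.linspace(lo, hi, 400)
    scores = np.empty_like(f_grid)
    for i, f in enumerate(f_grid):
        nu_pred = np.sqrt(np.arange(1, int(0.23 / f) + 2) * f)
        nu_pred = nu_pred[nu_pred < 0.48]
        scores[i] = np.interp(nu_pred, nu, dips).mean() if len(nu_pred) else np.inf
    f_coarse = float(f_grid[np.argmin(scores)])

    # unique minima-to-order assignment around the coarse alignment,
    # then a least-squares refit of nu_m^2 = m*F
    orders = np.arange(1, int(0.23 / f_coarse) + 2)
    nu_pred = np.sqrt(orders * f_coarse)
    keep = nu_pred < 0.48
    orders, nu_pred = orders[keep], nu_pred[keep]
    best: dict[int, tuple[float, int]] = {}  # minimum index -> (|dev|, order)
    for m, np_ in zip(orders, nu_pred, strict=True):
        k = int(np.argmin(np.abs(nu_min - np_)))
        dev = abs(nu_min[k] - np_)
        spacing = np_ * (math.sqrt((m + 1) / m) - 1.0)
        if dev < 0.4 * spacing and (k not in best or dev < best[k][0]):
            best[k] = (dev, int(m))
    if not best:
        return FresnelEstimate(f_initial, warning=True)
    m_arr = np.array([m for _, m in best.values()], dtype=float)
    nu_arr = np.array([nu_min[k] for k in best])
    f_fit = float(np.sum(m_arr * nu_arr**2) / np.sum(m_arr**2))
    return FresnelEstimate(min(max(f_fit, lo), hi), warning=False, minima_nu=nu_arr)
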