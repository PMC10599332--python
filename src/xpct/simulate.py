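"""Synthetic data generation: layered phantoms and the Fresnel forward model.

The phantom emulates a resin-embedded eye-like sample: nested concentric
shells ("sclera", "rods and cones", "ganglion cell layer", ...) with
per-layer optical constants (delta, beta), optionally with seeded
spherical "cells" inside one layer and a heavy-atom stain added to
selected layers via the beta/delta increments of the number-density
relation.

The forward model is a parallel-beam projection approximation: per view,
line integrals of delta and beta give the exit wave
``t = exp(-OD/2 + i*phi)`` with ``phi = -(2*pi/lambda) * integral(delta)``,
which is propagated to the detector with a single-Fourier-transform
Fresnel transfer function parameterised solely by the Fresnel number F.
Detector effects (Poisson noise, static per-column gain errors that
produce ring artifacts, hot pixels) are applied last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from skimage.transform import radon

from .optics import ScatteringTable, beta_from_number_density, fresnel_number, wavelength_from_energy

__all__ = [
    "PhantomVolume",
    "AcquisitionGeometry",
    "DetectorParams",
    "HologramStack",
    "make_layer_phantom",
    "add_stain",
    "default_retina_phantom",
    "project",
    "project_stack",
    "fresnel_propagate",
    "propagate_field",
    "simulate_detector",
    "simulate_scan",
]


@dataclass
class PhantomVolume:
    """Labelled 3D volume with per-label optical constants.

    ``labels`` is (nz, ny, nx) integer, 0 = background resin; materials
    maps every present label to (delta, beta) valid at ``energy`` keV.
    """

    labels: np.ndarray
    voxel_size: float  # nm
    energy: float  # keV at which materials are stated
    materials: dict[int, tuple[float, float]]
    layer_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (nz, ny, nx)")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels without material entry: {sorted(missing)}")
        for lab, (d, b) in self.materials.items():
            if d < 0 or b < 0:
                raise ValueError(f"negative delta/beta for label {lab}")
        if self.voxel_size <= 0 or self.energy <= 0:
            raise ValueError("voxel_size and energy must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_of(self, name: str) -> int:
        for lab, nm in self.layer_names.items():
            if nm == name:
                return lab
        raise KeyError(f"no layer named {name!r}")

    def material_volume(self) -> np.ndarray:
        """Complex (delta + i*beta) per voxel."""
        out = np.zeros(self.labels.shape, dtype=np.complex128)
        for lab, (d, b) in self.materials.items():
            if lab == 0 and d == 0 and b == 0:
                continue
            out[self.labels == lab] = d + 1j * b
        return out

    def with_materials(self, materials: Mapping[int, tuple[float, float]],
                       energy: float | None = None) -> "PhantomVolume":
        new = replace(self, materials=dict(materials),
                      energy=self.energy if energy is None else energy)
        # label geometry is shared, so the label-sinogram cache carries over
        if hasattr(self, "_cache"):
            new._cache = self._cache
        return new


@dataclass
class AcquisitionGeometry:
    """Parallel-beam scan geometry."""

    energy: float  # keV
    pixel_size: float  # nm
    distance: float  # mm
    angles: np.ndarray  # degrees, strictly increasing, in [0, 360)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1 or len(self.angles) < 1:
            raise ValueError("angles must be a 1D sequence")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")

    @property
    def n_projections(self) -> int:
        return len(self.angles)

    @property
    def wavelength(self) -> float:
        return wavelength_from_energy(self.energy)

    @property
    def fresnel(self) -> float:
        return fresnel_number(self.pixel_size, self.distance, self.energy)

    @classmethod
    def over_360(cls, energy: float, pixel_size: float, distance: float,
                 n_projections: int) -> "AcquisitionGeometry":
        angles = np.arange(n_projections) * 360.0 / n_projections
        return cls(energy, pixel_size, distance, angles)


@dataclass
class DetectorParams:
    """Detector noise model parameters.

    Defaults emulate a synchrotron scan that nearly fills a 16-bit
    detector (tens of kilo-counts per pixel), with sub-percent static
    column-gain errors (the source of ring artifacts) and a sparse
    population of hot pixels.
    """

    photons_per_pixel: float = 30000.0
    hot_pixel_rate: float = 1e-4
    column_gain_sigma: float = 0.005
    dark_level: float = 10.0
    n_flats: int = 10
    n_darks: int = 10


@dataclass
class HologramStack:
    """Per-angle detector frames plus reference frames and geometry."""

    frames: np.ndarray  # (n_angles, nz, nx)
    flats: np.ndarray  # (n_flats, nz, nx)
    darks: np.ndarray  # (n_darks, nz, nx)
    geometry: AcquisitionGeometry
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_angles, nz, nx)")
        if self.flats.shape[1:] != self.frames.shape[1:] or self.darks.shape[1:] != self.frames.shape[1:]:
            raise ValueError("flats/darks must match frame shape")
        if np.any(self.frames < 0) or np.any(self.flats < 0) or np.any(self.darks < 0):
            raise ValueError("intensities must be non-negative")
        if self.darks.mean() >= self.flats.mean():
            raise ValueError("darks must be darker than flats")


def make_layer_phantom(
    shape: tuple[int, int, int],
    layer_spec: Sequence[tuple[str, float, float, float]],
    voxel_size: float,
    energy: float,
    seed: int = 0,
    cells: dict | None = None,
) -> PhantomVolume:
    """Concentric-shell phantom from an outermost-first layer list.

    ``layer_spec`` rows are (name, outer_radius_fraction, delta, beta)
    with radius fractions strictly decreasing inward, in (0, 1] relative
    to half the in-plane width.  Shells are nested and non-overlapping;
    label i+1 is the i-th listed layer, label 0 the background resin.

    ``cells`` optionally seeds spherical inclusions inside one named
    layer (mimicking somata in the ganglion cell layer):
    ``{"layer": name, "n": int, "radius": voxels, "delta": d, "beta": b}``.
    """
    fracs = [s[1] for s in layer_spec]
    if any(not (0 < f <= 1) for f in fracs):
        raise ValueError("radius fractions must lie in (0, 1]")
    if any(b >= a for a, b in zip(fracs, fracs[1:], strict=False)) or len(set(fracs)) != len(fracs):
        raise ValueError("radius fractions must be strictly decreasing inward")

    nz, ny, nx = shape
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    # sphere centered on the rotation axis; integer-center convention
    cz, cy, cx = nz // 2, ny // 2, nx // 2
    r_unit = min(ny, nx) / 2.0
    r2 = ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2).astype(float)

    labels = np.zeros(shape, dtype=np.int16)
    materials: dict[int, tuple[float, float]] = {0: (0.0, 0.0)}
    names: dict[int, str] = {0: "resin"}
    for i, (name, frac, d, b) in enumerate(layer_spec):
        lab = i + 1
        labels[r2 <= (frac * r_unit) ** 2] = lab
        materials[lab] = (float(d), float(b))
        names[lab] = name

    if cells:
        target = [lab for lab, nm in names.items() if nm == cells["layer"]]
        if not target:
            raise ValueError(f"no layer named {cells['layer']!r}")
        lab_cell = max(materials) + 1
        rng = np.random.default_rng(seed)
        rad = float(cells.get("radius", 3.0))
        inside = np.argwhere(labels == target[0])
        if len(inside):
            picks = inside[rng.choice(len(inside), size=min(cells.get("n", 30), len(inside)), replace=False)]
            for pz, py, px in picks:
                z0, z1 = max(0, int(pz - rad)), min(nz, int(pz + rad + 1))
                y0, y1 = max(0, int(py - rad)), min(ny, int(py + rad + 1))
                x0, x1 = max(0, int(px - rad)), min(nx, int(px + rad + 1))
                sz, sy, sx = np.ogrid[z0:z1, y0:y1, x0:x1]
                mask = (sz - pz) ** 2 + (sy - py) ** 2 + (sx - px) ** 2 <= rad**2
                sub = labels[z0:z1, y0:y1, x0:x1]
                sub[mask & (sub == target[0])] = lab_cell
        materials[lab_cell] = (float(cells.get("delta", 0.0)), float(cells.get("beta", 0.0)))
        names[lab_cell] = cells["layer"] + "_cells"

    return PhantomVolume(labels, voxel_size, energy, materials, names)


def add_stain(
    phantom: PhantomVolume,
    layer_name: str,
    rho_a: float,
    table: ScatteringTable,
    energy: float | None = None,
) -> PhantomVolume:
    """Return a copy with ``rho_a`` atoms/nm^3 of a stain added to one layer.

    beta is raised by r0*lambda^2*rho_a*f2/(2*pi) and delta by the
    analogous f1 term, both interpolated from the element table at the
    phantom's energy.
    """
    e = phantom.energy if energy is None else energy
    f1, f2 = table.interpolate(e)
    d_beta = beta_from_number_density(rho_a, f2, e)
    d_delta = beta_from_number_density(rho_a, f1, e)  # same prefactor, f1 in place of f2
    lab = phantom.label_of(layer_name)
    mats = dict(phantom.materials)
    d0, b0 = mats[lab]
    mats[lab] = (d0 + d_delta, b0 + d_beta)
    return phantom.with_materials(mats, energy=e)


def default_retina_phantom(
    shape: tuple[int, int, int] = (256, 256, 256),
    voxel_size: float = 650.0,
    energy: float = 16.0,
    delta_beta: float = 35.0,
    mu_tissue_per_vox: float = 4e-4,
    seed: int = 0,
) -> PhantomVolume:
    """Five-layer eye-like phantom with soft-tissue optical constants.

    Layer betas are set so the densest layer attenuates by
    ``mu_tissue_per_vox`` per voxel; all unstained layers share a common
    delta/beta ratio (default 35, a soft-tissue value at 16 keV).
    """
    lam = wavelength_from_energy(energy)
    beta_ref = mu_tissue_per_vox / voxel_size * lam / (4.0 * math.pi)
    # relative tissue densities, outermost first
    spec = [
        ("sclera", 0.92, 1.00),
        ("choroid", 0.80, 0.80),
        ("rods_cones", 0.66, 0.90),
        ("nuclear_plexiform", 0.50, 0.60),
        ("ganglion", 0.32, 0.45),
    ]
    layers = [(name, frac, delta_beta * beta_ref * rel, beta_ref * rel) for name, frac, rel in spec]
    return make_layer_phantom(
        shape, layers, voxel_size, energy, seed=seed,
        cells={"layer": "ganglion", "n": 40, "radius": 4.0,
               "delta": delta_beta * beta_ref * 0.75, "beta": beta_ref * 0.75},
    )


def _label_sinograms(phantom: PhantomVolume, angles: np.ndarray) -> dict[int, np.ndarray]:
    """Line integrals (in voxel units) of each non-background label
    indicator, per angle: arrays of shape (n_angles, nz, nx).

    Computed slice-wise with the Radon transform; cached on the phantom
    instance keyed by the angle grid.
    """
    key = ("_sino_cache", tuple(np.round(angles, 9)))
    cache = getattr(phantom, "_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    nz, ny, nx = phantom.shape
    if ny != nx:
        raise ValueError("in-plane shape must be square for projection")
    out: dict[int, np.ndarray] = {}
    for lab in phantom.materials:
        if lab == 0:
            continue
        sino = np.empty((len(angles), nz, nx), dtype=np.float64)
        for iz in range(nz):
            ind = (phantom.labels[iz] == lab).astype(np.float64)
            if ind.any():
                # radon returns (detector, n_angles)
                sino[:, iz, :] = radon(ind, theta=angles, circle=True).T
            else:
                sino[:, iz, :] = 0.0
        out[lab] = sino
    object.__setattr__(phantom, "_cache", (key, out))
    return out


def project_stack(phantom: PhantomVolume, angles: np.ndarray,
                  energy: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(phase, optical density) projections for all angles.

    Returns two arrays of shape (n_angles, nz, nx): the projected phase
    magnitude (2*pi/lambda) * integral(delta) in radians, and the
    optical density integral(mu) (dimensionless).  The physical exit
    wave uses the negative of the returned phase.
    """
    e = phantom.energy if energy is None else energy
    lam = wavelength_from_energy(e)
    sinos = _label_sinograms(phantom, np.asarray(angles, dtype=float))
    shape = (len(angles),) + (phantom.shape[0], phantom.shape[2])
    proj_delta = np.zeros(shape)
    proj_beta = np.zeros(shape)
    for lab, sino in sinos.items():
        d, b = phantom.materials[lab]
        if d:
            proj_delta += d * sino
        if b:
            proj_beta += b * sino
    t = phantom.voxel_size  # line-integral step in nm
    phase = (2.0 * math.pi / lam) * proj_delta * t
    od = (4.0 * math.pi / lam) * proj_beta * t
    return phase, od


def project(phantom: PhantomVolume, angle: float,
            energy: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Single-angle (phase, optical density) projection, shape (nz, nx)."""
    phase, od = project_stack(phantom, np.array([angle % 360.0]), energy=energy)
    return phase[0], od[0]


def _transfer_function(shape: tuple[int, int], fresnel: float) -> np.ndarray:
    ny, nx = shape
    nu_y = np.fft.fftfreq(ny)[:, None]
    nu_x = np.fft.fftfreq(nx)[None, :]
    chi = math.pi * (nu_y**2 + nu_x**2) / fresnel
    return np.exp(-1j * chi)


def propagate_field(wavefield: np.ndarray, fresnel: float) -> np.ndarray:
    """Free-space Fresnel propagation of a complex field (no padding).

    The transfer function exp(-i*pi*|nu|^2/F) is unitary; negative F
    propagates backwards and exactly undoes a forward step.
    """
    field = np.asarray(wavefield, dtype=np.complex128)
    if not np.all(np.isfinite(field)):
        raise ValueError("wavefield must be finite")
    if fresnel == 0:
        raise ValueError("fresnel number must be nonzero")
    return np.fft.ifft2(np.fft.fft2(field) * _transfer_function(field.shape, fresnel))


def fresnel_propagate(wavefield: np.ndarray, fresnel: float, pad: bool = True) -> np.ndarray:
    """Detector-plane intensity |psi|^2 after Fresnel propagation.

    With ``pad`` (default) the field is edge-replicated to twice its
    size before the Fourier step and cropped after, suppressing periodic
    wrap-around from the FFT.
    """
    if fresnel <= 0:
        raise ValueError("fresnel number must be positive")
    field = np.asarray(wavefield, dtype=np.complex128)
    if not np.all(np.isfinite(field)):
        raise ValueError("wavefield must be finite")
    if pad:
        ny, nx = field.shape
        py, px = ny // 2, nx // 2
        field = np.pad(field, ((py, py), (px, px)), mode="edge")
        out = propagate_field(field, fresnel)
        out = out[py : py + ny, px : px + nx]
    else:
        out = propagate_field(field, fresnel)
    return np.abs(out) ** 2


def simulate_detector(
    intensity: np.ndarray,
    photons_per_pixel: float,
    hot_pixel_rate: float = 0.0,
    column_gain_sigma: float = 0.0,
    seed: int = 0,
    column_gains: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Convert a relative intensity frame to noisy detector counts.

    Expected counts are intensity * photons_per_pixel * column_gain;
    per-column gains are static over a scan (pass ``column_gains`` to
    share them between frames and flats — that correlation is what turns
    into ring artifacts after reconstruction).  Poisson counts are
    drawn, then exactly round(rate * n_pixels) hot pixels are overwritten
    with extreme values.  Deterministic for a fixed seed.
    """
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be positive")
    intensity = np.asarray(intensity, dtype=np.float64)
    if rng is None:
        rng = np.random.default_rng(seed)
    if column_gains is None:
        column_gains = 1.0 + column_gain_sigma * rng.standard_normal(intensity.shape[-1])
    expected = np.clip(intensity, 0, None) * photons_per_pixel * column_gains[None, :]
    frame = rng.poisson(expected).astype(np.float64)
    n_hot = int(round(hot_pixel_rate * intensity.size))
    if n_hot > 0:
        flat_idx = rng.choice(intensity.size, size=n_hot, replace=False)
        hot_vals = photons_per_pixel * rng.uniform(20.0, 50.0, size=n_hot)
        frame.flat[flat_idx] = hot_vals
    return frame


def simulate_scan(
    phantom: PhantomVolume,
    geometry: AcquisitionGeometry,
    detector: DetectorParams | None = DetectorParams(),
    seed: int = 0,
    axis_offset: float = 0.0,
) -> HologramStack:
    """Full synthetic acquisition: project, propagate, detect.

    Per angle the exit wave ``exp(-OD/2 - i*phase)`` is Fresnel-propagated
    at the geometry's F and recorded with the detector model; flats and
    darks share the same static column gains.  ``detector=None`` yields
    ideal noiseless intensities (flats of ones, darks of zeros-plus-eps).
    A nonzero ``axis_offset`` (pixels) displaces the rotation axis from
    the detector center, emulating a miscentered scan.
    """
    phase, od = project_stack(phantom, geometry.angles, energy=geometry.energy)
    if axis_offset:
        from scipy import ndimage  # lazy; only needed for miscentered scans

        phase = np.stack([ndimage.shift(p, (0.0, axis_offset), order=1, mode="nearest") for p in phase])
        od = np.stack([ndimage.shift(p, (0.0, axis_offset), order=1, mode="nearest") for p in od])
    F = geometry.fresnel
    n_angles, nz, nx = phase.shape
    rng = np.random.default_rng(seed)

    intensities = np.empty_like(phase)
    for i in range(n_angles):
        wave = np.exp(-0.5 * od[i] - 1j * phase[i])
        intensities[i] = fresnel_propagate(wave, F)

    if detector is None:
        flats = np.ones((1, nz, nx))
        darks = np.zeros((1, nz, nx))
        return HologramStack(intensities, flats, darks, geometry, seed)

    gains = 1.0 + detector.column_gain_sigma * rng.standard_normal(nx)
    frames = np.empty_like(intensities)
    for i in range(n_angles):
        frames[i] = simulate_detector(
            intensities[i], detector.photons_per_pixel, detector.hot_pixel_rate,
            rng=rng, column_gains=gains,
        )
    flats = np.stack([
        simulate_detector(np.ones((nz, nx)), detector.photons_per_pixel,
                          detector.hot_pixel_rate * 0.0, rng=rng, column_gains=gains)
        for _ in range(detector.n_flats)
    ])
    darks = np.stack([
        rng.poisson(detector.dark_level, size=(nz, nx)).astype(np.float64)
        for _ in range(detector.n_darks)
    ])
    return HologramStack(frames, flats, darks, geometry, seed)
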