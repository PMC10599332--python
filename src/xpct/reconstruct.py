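"""Parallel-beam filtered backprojection over 360 degrees.

Thin wrapper around scikit-image's ``iradon`` (frequency-domain ramp
a.k.a. Ram-Lak filtering on zero-padded projection rows, linear
interpolation backprojection), assembling per-slice sinograms from a
projection stack and recording units and provenance.  All views of a
360-degree scan are backprojected with uniform weight; no 180-degree
folding, which keeps the result robust to residual axis error.

Output attenuation units are 1/voxel; division by the voxel size (nm)
converts to 1/nm for the optics-module density chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon

__all__ = ["ReconVolume", "fbp", "reconstruct_volume"]

_FILTERS = {"ram-lak": "ramp", "none": None}


@dataclass
class ReconVolume:
    """Reconstructed 3D volume with mandatory unit tag."""

    values: np.ndarray  # (nz, ny, nx)
    units: str  # attenuation_per_voxel | phase_per_voxel
    voxel_size: float  # nm
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units not in ("attenuation_per_voxel", "phase_per_voxel"):
            raise ValueError(f"unknown units {self.units!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstruction must be finite")


def fbp(sinogram: np.ndarray, angles: np.ndarray, filter_name: str = "ram-lak") -> np.ndarray:
    """Filtered backprojection of one (angle x detector) sinogram.

    Returns a square slice in line-integral-per-voxel units (1/voxel
    when the sinogram holds -ln(I) optical densities).
    """
    sino = np.asarray(sinogram, dtype=np.float64)
    angles = np.asarray(angles, dtype=float)
    if sino.ndim != 2:
        raise ValueError("sinogram must be 2D (angle x detector)")
    if sino.shape[0] != len(angles):
        raise ValueError(
            f"sinogram has {sino.shape[0]} rows but {len(angles)} angles were given"
        )
    if len(angles) < 2:
        raise ValueError("need at least two angles")
    if filter_name not in _FILTERS:
        raise ValueError(f"filter must be one of {sorted(_FILTERS)}")
    return iradon(
        sino.T,
        theta=angles,
        filter_name=_FILTERS[filter_name],
        interpolation="linear",
        circle=True,
        output_size=sino.shape[1],
    )


def backproject_ray(n: int, angle: float) -> np.ndarray:
    """Unfiltered backprojection of a single-ray impulse at one angle —
    a straight line through the slice along that ray (geometry probe)."""
    sino = np.zeros((2, n))
    sino[0, n // 2] = 1.0
    # second (empty) view only to satisfy the two-angle minimum
    return fbp(sino, np.array([angle, angle + 90.0]), filter_name="none")


def reconstruct_volume(
    projections: np.ndarray,
    angles: np.ndarray,
    axis_offset: float = 0.0,
    units: str = "attenuation_per_voxel",
    voxel_size: float = 1.0,
    ring_filter=None,
    filter_name: str = "ram-lak",
    provenance: dict | None = None,
) -> ReconVolume:
    """Slice-by-slice FBP of a projection stack (n_angles, nz, nx).

    ``projections`` are -ln(I) sinogram frames for attenuation volumes
    or retrieved phase maps for phase volumes.  ``axis_offset`` (pixels)
    is removed before backprojection; ``ring_filter`` is an optional
    callable applied to each assembled (angle x detector) sinogram.
    """
    from .preprocess import apply_axis_shift  # local import to avoid cycle

    proj = np.asarray(projections, dtype=np.float64)
    if proj.ndim != 3:
        raise ValueError("projections must be (n_angles, nz, nx)")
    if proj.shape[0] != len(angles):
        raise ValueError("projection count does not match angle count")
    if axis_offset:
        proj = apply_axis_shift(proj, axis_offset)
    n_angles, nz, nx = proj.shape
    volume = np.empty((nz, nx, nx), dtype=np.float32)
    for iz in range(nz):
        sino = proj[:, iz, :]
        if ring_filter is not None:
            sino = ring_filter(sino)
        volume[iz] = fbp(sino, angles, filter_name=filter_name)
    prov = dict(provenance or {})
    prov.update(
        n_projections=int(n_angles),
        axis_offset=float(axis_offset),
        filter=filter_name,
        ring_filter=ring_filter is not None,
    )
    return ReconVolume(volume, units, voxel_size, prov)
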