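"""Reading and writing pipeline artifacts.

Hologram stacks travel as multipage TIFF (one page per angle) with
separate flat/dark TIFFs and a JSON metadata sidecar, or as a single
HDF5 container with the same fields.  Reconstructed volumes are written
as 32-bit float multipage TIFF or HDF5, provenance embedded in the
sidecar / HDF5 attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .reconstruct import ReconVolume
from .simulate import AcquisitionGeometry, HologramStack

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_stack_hdf5",
    "read_stack_hdf5",
    "write_volume",
    "read_volume",
]


def _geometry_meta(geom: AcquisitionGeometry) -> dict:
    return {
        "energy_keV": geom.energy,
        "pixel_size_nm": geom.pixel_size,
        "distance_mm": geom.distance,
        "angles_deg": [float(a) for a in geom.angles],
        "fresnel": geom.fresnel,
    }


def _geometry_from_meta(meta: dict) -> AcquisitionGeometry:
    for key in ("energy_keV", "pixel_size_nm", "distance_mm", "angles_deg"):
        if key not in meta:
            raise ValueError(f"metadata sidecar missing required key {key!r}")
    return AcquisitionGeometry(
        energy=float(meta["energy_keV"]),
        pixel_size=float(meta["pixel_size_nm"]),
        distance=float(meta["distance_mm"]),
        angles=np.asarray(meta["angles_deg"], dtype=float),
    )


def write_stack_tiff(stack: HologramStack, directory: str | Path, extra_meta: dict | None = None) -> Path:
    """Write frames/flats/darks TIFFs plus a JSON sidecar; returns the
    sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "frames.tif", stack.frames.astype(np.float32))
    tifffile.imwrite(directory / "flats.tif", stack.flats.astype(np.float32))
    tifffile.imwrite(directory / "darks.tif", stack.darks.astype(np.float32))
    meta = {"seed": stack.seed, **_geometry_meta(stack.geometry), **(extra_meta or {})}
    sidecar = directory / "metadata.json"
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_stack_tiff(directory: str | Path) -> HologramStack:
    directory = Path(directory)
    sidecar = directory / "metadata.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(directory / "frames.tif").astype(np.float64)
    flats = tifffile.imread(directory / "flats.tif").astype(np.float64)
    darks = tifffile.imread(directory / "darks.tif").astype(np.float64)
    if flats.ndim == 2:
        flats = flats[None]
    if darks.ndim == 2:
        darks = darks[None]
    geom = _geometry_from_meta(meta)
    if frames.shape[0] != geom.n_projections:
        raise ValueError("sidecar angle count does not match frame count")
    return HologramStack(frames, flats, darks, geom, seed=int(meta.get("seed", 0)))


def write_stack_hdf5(stack: HologramStack, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=stack.frames.astype(np.float32))
        fh.create_dataset("flats", data=stack.flats.astype(np.float32))
        fh.create_dataset("darks", data=stack.darks.astype(np.float32))
        fh.create_dataset("angles_deg", data=np.asarray(stack.geometry.angles))
        for k, v in _geometry_meta(stack.geometry).items():
            if k != "angles_deg":
                fh.attrs[k] = v
        fh.attrs["seed"] = stack.seed
    return path


def read_stack_hdf5(path: str | Path) -> HologramStack:
    with h5py.File(path, "r") as fh:
        geom = AcquisitionGeometry(
            energy=float(fh.attrs["energy_keV"]),
            pixel_size=float(fh.attrs["pixel_size_nm"]),
            distance=float(fh.attrs["distance_mm"]),
            angles=fh["angles_deg"][()],
        )
        return HologramStack(
            fh["frames"][()].astype(np.float64),
            fh["flats"][()].astype(np.float64),
            fh["darks"][()].astype(np.float64),
            geom,
            seed=int(fh.attrs.get("seed", 0)),
        )


def write_volume(vol: ReconVolume, path: str | Path) -> Path:
    """Write a reconstructed volume (.tif or .h5 by extension)."""
    path = Path(path)
    meta = {"units": vol.units, "voxel_size_nm": vol.voxel_size, "provenance": vol.provenance}
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("volume", data=vol.values.astype(np.float32))
            fh.attrs["meta"] = json.dumps(meta)
    else:
        tifffile.imwrite(path, vol.values.astype(np.float32))
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            values = fh["volume"][()]
            meta = json.loads(fh.attrs["meta"])
    else:
        values = tifffile.imread(path)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing volume sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
    return ReconVolume(
        values.astype(np.float32), meta["units"], float(meta["voxel_size_nm"]),
        meta.get("provenance", {}),
    )
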