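"""Scalar X-ray optical-constant arithmetic.

The chain implemented here links the imaginary part of the refractive
index ``n = 1 - delta + i*beta`` to measurable attenuation and to the
number density of a heavy-atom stain:

    beta  = r0 * lambda^2 * rho_a * f2 / (2*pi)
    mu    = 4*pi*beta / lambda
    rho_a = mu / (2 * r0 * lambda * f2)

with ``r0`` the Thomson scattering length, ``rho_a`` the atomic number
density and ``f2`` the imaginary atomic scattering factor.  From
``rho_a`` follow a mass density ``rho = rho_a * A / N_A`` and a
Wigner-Seitz mean interatomic distance ``(3/(4*pi*rho_a))**(1/3)``.

Units: energies in keV, lengths in nm, number densities in atoms/nm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import HC_KEV_NM, N_AVOGADRO, R0_NM

__all__ = [
    "EnergySpec",
    "ScatteringTable",
    "OpticalConstants",
    "DensityResult",
    "wavelength_from_energy",
    "fresnel_number",
    "beta_from_number_density",
    "mu_from_beta",
    "beta_from_mu",
    "number_density_from_mu",
    "mass_density",
    "mean_distance",
    "delta_beta_ratio",
    "implied_f2",
    "load_scattering_table",
    "bundled_table",
    "BUNDLED_ELEMENTS",
]

#: Elements with scattering tables shipped in ``xpct/data``.
BUNDLED_ELEMENTS = ("Nd", "Os", "U", "I")


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in nm for an energy in keV.

    Uses hc = 12.39842 keV*Angstrom, e.g. 16 keV -> 0.077490 nm.
    """
    if energy_kev <= 0:
        raise ValueError(f"energy must be positive, got {energy_kev}")
    return HC_KEV_NM / energy_kev


@dataclass(frozen=True)
class EnergySpec:
    """Photon energy with its derived wavelength."""

    energy: float  # keV

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("energy must be positive")

    @property
    def wavelength(self) -> float:
        """Wavelength in nm."""
        return wavelength_from_energy(self.energy)


def fresnel_number(pixel_size_nm: float, distance_mm: float, energy_kev: float) -> float:
    """Fresnel number F = px^2 / (z * lambda), dimensionless.

    F governs the diffraction regime of a propagation-based imaging
    setup; F << 1 is the holographic regime.

    Parameters
    ----------
    pixel_size_nm : effective (demagnified) pixel size in nm.
    distance_mm : (effective) propagation distance in mm.
    energy_kev : photon energy in keV.
    """
    if pixel_size_nm < 0:
        raise ValueError("pixel size must be non-negative")
    if distance_mm <= 0 or energy_kev <= 0:
        raise ValueError("distance and energy must be positive")
    lam = wavelength_from_energy(energy_kev)
    return pixel_size_nm**2 / (distance_mm * 1e6 * lam)


def beta_from_number_density(
    rho_a: float, f2: float, energy_kev: float, *, r0_nm: float = R0_NM
) -> float:
    """beta = r0 * lambda^2 * rho_a * f2 / (2*pi).

    ``rho_a`` in atoms/nm^3, ``f2`` the imaginary scattering factor.
    """
    if rho_a < 0 or f2 < 0:
        raise ValueError("rho_a and f2 must be non-negative")
    lam = wavelength_from_energy(energy_kev)
    return r0_nm * lam**2 * rho_a * f2 / (2.0 * math.pi)


def mu_from_beta(beta: float, energy_kev: float) -> float:
    """Linear attenuation coefficient mu = 4*pi*beta/lambda, in 1/nm."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return 4.0 * math.pi * beta / wavelength_from_energy(energy_kev)


def beta_from_mu(mu_per_nm: float, energy_kev: float) -> float:
    """Inverse of :func:`mu_from_beta`."""
    if mu_per_nm < 0:
        raise ValueError("mu must be non-negative")
    return mu_per_nm * wavelength_from_energy(energy_kev) / (4.0 * math.pi)


def number_density_from_mu(
    delta_mu: float,
    f2: float,
    energy_kev: float,
    *,
    voxel_size_nm: float | None = None,
    r0_nm: float = R0_NM,
) -> float:
    """Stain number density rho_a = delta_mu / (2 * r0 * lambda * f2), atoms/nm^3.

    ``delta_mu`` is the excess attenuation attributed to the stain, in
    1/nm — or in 1/voxel if ``voxel_size_nm`` is given, in which case it
    is divided by the voxel size first.
    """
    if delta_mu < 0:
        raise ValueError("delta_mu must be non-negative")
    if f2 <= 0:
        raise ValueError("f2 must be positive")
    if voxel_size_nm is not None:
        if voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")
        delta_mu = delta_mu / voxel_size_nm
    lam = wavelength_from_energy(energy_kev)
    return delta_mu / (2.0 * r0_nm * lam * f2)


def implied_f2(
    delta_mu_per_nm: float, rho_a: float, energy_kev: float, *, r0_nm: float = R0_NM
) -> float:
    """Diagnostic: the f2 value that would make a (delta_mu, rho_a) pair
    consistent with rho_a = delta_mu/(2*r0*lambda*f2).

    Useful for auditing published attenuation/density pairs whose f2
    source is unstated.
    """
    if rho_a <= 0:
        raise ValueError("rho_a must be positive")
    lam = wavelength_from_energy(energy_kev)
    return delta_mu_per_nm / (2.0 * r0_nm * lam * rho_a)


def mass_density(rho_a: float, atomic_mass: float) -> float:
    """Mass density rho = rho_a * A / N_A in g/cm^3.

    ``rho_a`` in atoms/nm^3, ``atomic_mass`` A in g/mol.
    """
    if rho_a < 0:
        raise ValueError("rho_a must be non-negative")
    if atomic_mass <= 0:
        raise ValueError("atomic mass must be positive")
    # 1 nm^-3 = 1e21 cm^-3
    return rho_a * 1e21 * atomic_mass / N_AVOGADRO


def mean_distance(rho_a: float) -> float:
    """Wigner-Seitz radius (3/(4*pi*rho_a))**(1/3) in nm.

    The radius of the sphere whose volume is the volume per atom; used
    as the mean distance between stain atoms.
    """
    if rho_a <= 0:
        raise ValueError("rho_a must be positive")
    return (3.0 / (4.0 * math.pi * rho_a)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive index parts n = 1 - delta + i*beta at one energy."""

    delta: float
    beta: float
    energy: float  # keV

    def __post_init__(self) -> None:
        if self.delta < 0 or self.beta < 0:
            raise ValueError("delta and beta must be non-negative for materials in scope")

    @property
    def delta_beta(self) -> float:
        return self.delta / self.beta if self.beta > 0 else math.inf

    def mu_per_nm(self) -> float:
        return mu_from_beta(self.beta, self.energy)


@dataclass(frozen=True)
class DensityResult:
    """Stain density summary: number density, mass density, mean distance."""

    number_density: float  # atoms/nm^3
    mass_density: float  # g/cm^3
    mean_distance: float  # nm

    @classmethod
    def from_number_density(cls, rho_a: float, atomic_mass: float) -> "DensityResult":
        return cls(
            number_density=rho_a,
            mass_density=mass_density(rho_a, atomic_mass),
            mean_distance=mean_distance(rho_a) if rho_a > 0 else math.inf,
        )


class ScatteringTable:
    """Tabulated atomic scattering factors (E, f1, f2) for one element.

    Henke forward-scattering convention: f1 ~= Z + f', f2 = f''.
    Interpolation is linear between nodes and exact at nodes; no
    extrapolation outside the tabulated range.
    """

    def __init__(
        self,
        symbol: str,
        Z: int,
        A: float,
        energies_kev: Sequence[float],
        f1: Sequence[float],
        f2: Sequence[float],
    ) -> None:
        self.symbol = symbol
        self.Z = int(Z)
        self.A = float(A)
        e = np.asarray(energies_kev, dtype=float)
        if e.ndim != 1 or len(e) < 2:
            raise ValueError("need at least two tabulated energies")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        self.energies = e
        self.f1 = np.asarray(f1, dtype=float)
        self.f2 = np.asarray(f2, dtype=float)
        if self.f1.shape != e.shape or self.f2.shape != e.shape:
            raise ValueError("f1/f2 must match the energy grid")
        if np.any(self.f2 < 0):
            raise ValueError("f2 must be non-negative everywhere")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ScatteringTable({self.symbol}, Z={self.Z}, A={self.A}, "
            f"{len(self.energies)} rows, "
            f"{self.energies[0]:g}-{self.energies[-1]:g} keV)"
        )

    def _check_range(self, energy_kev: float) -> None:
        if not (self.energies[0] <= energy_kev <= self.energies[-1]):
            raise ValueError(
                f"energy {energy_kev} keV outside tabulated range "
                f"[{self.energies[0]:g}, {self.energies[-1]:g}] for {self.symbol}"
            )

    def interpolate(self, energy_kev: float) -> tuple[float, float]:
        """(f1, f2) linearly interpolated at ``energy_kev``."""
        self._check_range(energy_kev)
        return (
            float(np.interp(energy_kev, self.energies, self.f1)),
            float(np.interp(energy_kev, self.energies, self.f2)),
        )

    def f2_at(self, energy_kev: float) -> float:
        return self.interpolate(energy_kev)[1]

    def f_prime(self, energy_kev: float) -> float:
        """Anomalous correction f' = f1 - Z."""
        return self.interpolate(energy_kev)[0] - self.Z


def delta_beta_ratio(table: ScatteringTable, energy_kev: float) -> float:
    """delta/beta ratio per atom, (Z + f')/f'' = f1/f2.

    High values favour phase over absorption contrast; this is also the
    coupling parameter of homogeneous-object phase retrieval.
    """
    f1, f2 = table.interpolate(energy_kev)
    if f2 <= 0:
        raise ValueError(f"f2 is zero at {energy_kev} keV; ratio undefined")
    return f1 / f2


def load_scattering_table(path: str | Path) -> ScatteringTable:
    """Read a scattering table from a whitespace-separated text file.

    Expected format: one header line ``# symbol Z A`` followed by rows
    ``E f1 f2``.  Energies are in keV; the Henke ``.nff`` dialect with
    eV in the first column is auto-detected by magnitude (values above
    1000 are taken to be eV) and converted.
    """
    path = Path(path)
    header: list[str] = []
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if not header:
                    header = line.lstrip("#").split()
                continue
            parts = line.split()
            if len(parts) < 3:
                continue
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError:
                # .nff files may carry a non-numeric header line
                if not header and len(parts) >= 3:
                    header = parts[:3]
                continue
    if len(header) < 3:
        raise ValueError(f"{path}: missing '# symbol Z A' header")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    energies = arr[:, 0]
    if np.median(energies) > 1000.0:  # Henke .nff dialect: eV
        energies = energies / 1000.0
    try:
        Z = int(float(header[1]))
        A = float(header[2])
    except ValueError as exc:
        raise ValueError(f"{path}: header must be '# symbol Z A'") from exc
    return ScatteringTable(header[0], Z, A, energies, arr[:, 1], arr[:, 2])


def bundled_table(symbol: str) -> ScatteringTable:
    """Load one of the bundled element tables (Nd, Os, U, I)."""
    if symbol not in BUNDLED_ELEMENTS:
        raise KeyError(f"no bundled table for {symbol!r}; have {BUNDLED_ELEMENTS}")
    ref = resources.files("xpct.data").joinpath(f"{symbol.lower()}.tsv")
    with resources.as_file(ref) as p:
        return load_scattering_table(p)
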