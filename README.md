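# xpct

Propagation-based X-ray phase-contrast tomography (XPCT) of soft
tissue, end to end: forward simulation of inline holograms of layered
eye-like phantoms, projection-domain corrections, single-distance phase
retrieval (CTF and Paganin), filtered backprojection, and the
conversion of reconstructed attenuation histograms into heavy-atom
stain number densities.

It is aimed at people developing or validating staining and
quantification protocols for XPCT — where one wants to know, before or
instead of a beamtime, whether a stain load of so-many atoms per cubic
nanometre is recoverable from a single-distance scan, and how the
choice of stain element (Nd, Os, U, I) trades phase against absorption
contrast.

## The model in brief

With refractive index n = 1 − δ + iβ, a stain of number density ρa
(atoms/nm³) and imaginary scattering factor f″ contributes

    β = r0 λ² ρa f″ / 2π,   μ = 4πβ/λ   ⇒   ρa = Δμ / (2 r0 λ f″),

so the excess attenuation Δμ between a stained and an unstained sample
measures the stain load directly; ρ = ρa·A/N_A gives the mass density
and the Wigner–Seitz radius (3/4πρa)^⅓ the mean distance between stain
atoms.  Imaging is single-distance inline holography in parallel beam,
governed by the Fresnel number F = px²/(zλ); phase retrieval inverts
the linearized contrast transfer 2 sin χ·φ̂ − 2 cos χ·B̂ (χ = π|ν|²/F)
under a homogeneous-object δ/β coupling, or applies the Paganin
single-material filter.  Per-atom merit for phase contrast is
δ/β = f1/f2, bundled as text tables for Nd, Os, U and I (2–50 keV).

See `docs/methods.md` for assumptions, parameter defaults and
numerical choices.

## Worked example

Optical constants first:

```python
from xpct import optics
nd = optics.bundled_table("Nd")
print(optics.fresnel_number(650, 149, 16.0))   # 0.0366  (650 nm px, 149 mm, 16 keV)
print(nd.interpolate(16.0))                    # (59.93, 3.51) = (f1, f2)
for rho in (0.0117, 0.0105, 0.0249):
    print(rho, "->", round(optics.mean_distance(rho), 2), "nm")
# 0.0117 -> 2.73 nm   0.0105 -> 2.83 nm   0.0249 -> 2.12 nm
```

Then a closed loop — simulate a stained/unstained pair of tissue
phantoms carrying a known 0.012 Nd/nm³, run the full pipeline, and
recover the density:

```python
import numpy as np
from xpct import optics, simulate, preprocess, reconstruct, quantify

nd = optics.bundled_table("Nd")
E, rho_true = 16.0, 0.012
lam = optics.wavelength_from_energy(E)
beta = 4e-4 / 650.0 * lam / (4 * np.pi)          # tissue: 4e-4 /vox attenuation
ph = simulate.make_layer_phantom((16, 128, 128),
                                 [("tissue", 0.8, 35 * beta, beta)], 650.0, E)
ph_st = simulate.add_stain(ph, "tissue", rho_true, nd)
geom = simulate.AcquisitionGeometry.over_360(E, 650.0, 149.0, 180)

vols = {}
for tag, p, seed in (("stained", ph_st, 1), ("unstained", ph, 2)):
    stack = simulate.simulate_scan(p, geom, simulate.DetectorParams(), seed=seed)
    norm = preprocess.flat_dark_correct(stack)
    norm.frames, _ = preprocess.repair_stack(norm.frames)
    offset = preprocess.find_rotation_axis(norm)
    filtered = np.stack([quantify.suppress_phase(f, 8) for f in norm.frames])
    sino = -np.log(np.clip(filtered, 1e-6, None))
    vols[tag] = reconstruct.reconstruct_volume(
        sino, geom.angles, axis_offset=offset, voxel_size=650.0,
        ring_filter=preprocess.ring_filter_waveletfft)

report = quantify.quantify_stain(vols["stained"], vols["unstained"],
                                 roi=(28, 28, 72, 72), element=nd, energy=E,
                                 bin_width=2e-7, smooth_sigma=150.0,
                                 z_slices=slice(2, 14))
print(f"delta_mu      = {report.delta_mu:.3e} 1/vox")
print(f"number density= {report.density.number_density:.4f} Nd/nm^3 (true {rho_true})")
print(f"mass density  = {report.density.mass_density:.3e} g/cm^3")
print(f"mean distance = {report.density.mean_distance:.2f} nm")
```

prints (seeds as shown; ~20 s on one CPU):

```
delta_mu      = 1.260e-05 1/vox
number density= 0.0126 Nd/nm^3 (true 0.012)
mass density  = 3.027e-03 g/cm^3
mean distance = 2.66 nm
```

i.e. the pipeline recovers the injected stain load within 5% here: Δμ
is the difference of the two ROI histogram peaks, and the density chain
converts it with the table f″ at 16 keV.

The same workflows are scriptable from the shell (`xpct simulate`,
`xpct reconstruct --method ctf|paganin|none`, `xpct quantify`,
`xpct optics`), driven by a YAML config with per-stage sections; every
output carries a metadata sidecar with the effective config and seed.

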