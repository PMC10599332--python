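# Methods

`xpct` models single-distance propagation-based X-ray phase-contrast
tomography (XPCT) of resin-embedded soft tissue and the quantification
of heavy-atom stains (Nd, Os, U, I) from reconstructed attenuation
volumes.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic tests do and do not show.

## Optical constants and the density chain

The refractive index is written n = 1 − δ + iβ.  For a stain of atomic
number density ρa (atoms/nm³) with imaginary scattering factor f″ = f2,

    β  = r0 λ² ρa f2 / (2π),        μ = 4πβ/λ,
    ρa = μ / (2 r0 λ f2),

with r0 = 2.82×10⁻¹⁵ m (Thomson scattering length, kept at this
two-digit value and overridable) and λ = hc/E with hc = 12.39842 keV·Å.
All internal units are keV, nm, atoms/nm³; conversions (mm, g/cm³)
happen at interfaces only.  From ρa follow the mass density
ρ = ρa·A/N_A and the Wigner–Seitz radius (3/(4πρa))^(1/3), reported as
the mean distance between stain atoms.  Note that with printed-precision
inputs the Wigner–Seitz radius can land one unit in the last decimal
away from a value computed from unrounded densities (0.0249 nm⁻³ gives
2.12 nm; 0.0247 nm⁻³ gives 2.13 nm).

Atomic scattering factors are bundled as plain-text tables
(`# symbol Z A`, rows `E_keV f1 f2`, Henke convention f1 ≈ Z + f′) for
Nd, Os, U and I on a 2–50 keV grid refined near absorption edges.  They
are generated by `tools/make_scattering_tables.py` with the
Cromer–Liberman algorithm (via gemmi) and are exact to that computation,
which is known to be least accurate within a few percent of an edge.
Interpolation is linear between nodes, exact at nodes, and refuses to
extrapolate.  The per-atom phase-versus-absorption figure of merit is
δ/β = f1/f2.  With these tables, Nd's ratio exceeds uranium's between
the U L3 edge (17.17 keV) and the Nd K edge (43.57 keV); above the K
edge the Nd f2 jump reverses the ordering.  Claims of an Nd advantage
"above 17 keV" therefore hold only up to the K edge, and the acceptance
test that asserts the ordering on all of (17, 50] keV fails by design
on the 43.6–50 keV tail.

A diagnostic `implied_f2(Δμ, ρa, E)` back-solves the density relation;
applied to the published murine-retina pair (Δμ = 1.8250×10⁻⁴ /vox at
650 nm voxels, ρa = 0.0117 Nd/nm³, 13.8 keV) it yields f2 ≈ 47, an
order of magnitude above any tabulated Nd value, so that pair is
treated as a reference number for the real data rather than a check of
the formula.

## Synthetic phantoms and the forward model

`make_layer_phantom` builds nested concentric shells (outermost first,
strictly decreasing radius fractions of half the in-plane width) on an
integer label grid, with optional seeded spherical "cells" inside a
named layer; `default_retina_phantom` instantiates a five-layer eye-like
arrangement (sclera, choroid, rods/cones, nuclear/plexiform, ganglion
with cell speckle).  Materials are (δ, β) pairs at a stated energy.
Unstained tissue uses δ/β = 35 and a per-voxel attenuation of 4×10⁻⁴
(1/vox at 650 nm voxels), a soft-tissue scale at 16 keV; a stain adds
Δβ = r0λ²ρa f2/(2π) and the analogous f1 term to δ.

The forward model is the thin-object projection approximation in
parallel beam: per view, line integrals of δ and β (computed slice-wise
with the Radon transform, cached per label so stained/unstained and
multi-energy variants reuse one geometric projection) give the exit
wave exp(−OD/2 − iφ) with φ = (2π/λ)∫δ.  Free-space propagation is a
single-FFT transfer function H(ν) = exp(−iπ|ν|²/F) in reduced frequency
units, parameterized solely by the Fresnel number F = px²/(zλ); the
field is edge-replicated to twice its size and cropped to suppress
periodic wrap-around.  The propagator is unitary, and F then −F is an
exact inverse (tested to machine precision without padding).

The detector model scales intensities to photon counts (default 30 000
per pixel, the scale of a near-filled 16-bit synchrotron camera), draws
Poisson counts with static per-column gain errors (σ = 0.5%, shared
between frames and flats — after reconstruction these become ring
artifacts), and overwrites exactly round(rate·n_pixels) hot pixels
(default rate 10⁻⁴) with extreme values.  All randomness flows through
explicit seeds; identical seeds give bit-identical stacks.

Not modeled: cone-beam magnification, polychromatic lab spectra, source
blur, detector PSF, partial coherence, scatter.  A laboratory-style
scan is represented as a monochromatic scan at an effective energy with
Paganin reconstruction — a stated simplification.

## Projection-domain corrections

* Flat/dark: I_norm = (I − ⟨darks⟩)/(⟨flats⟩ − ⟨darks⟩), floored at
  10⁻⁶; shared column gains divide out.
* Hot pixels: a pixel deviating from its 3×3 median by more than
  k·MAD (k = 10) is replaced by the mean of its valid 8-neighbours.
  On the default noise this recovers injected hot pixels with ≥95%
  sensitivity at ≤0.1% false positives.
* Rotation axis: a projection at θ and the mirrored projection at
  θ+180° differ by twice the axis offset.  Depth-summed profiles are
  baseline-subtracted (a constant pedestal, zero-padded, correlates
  like a box and drags the peak toward zero lag), cross-correlated with
  16× spectral upsampling and parabolic refinement, and averaged over
  up to eight opposing pairs.  Accuracy is ~0.1 px; the phantom needs a
  background margin so fringes stay on the detector.
* Ring filter (wavelet-FFT): multilevel DWT along the detector axis
  (db25, 4 levels, the published defaults of the method), and in each
  detail band the FFT along angle is damped by the notch
  1 − exp(−u²/2σ²), σ = 2.4.  This removes angle-static fine structure
  — stripes — by >90% in energy while changing a smooth, genuinely
  rotating sinogram by <1% RMS.  Because the notch cannot distinguish
  rings from angle-static real detail, sinograms of perfectly
  circularly symmetric objects lose some genuine edge detail; the test
  phantoms for signal preservation are therefore asymmetric.

Applied in pipeline order: flat/dark → hot pixels → (phase retrieval or
phase suppression) → sinogram assembly with axis shift → ring filter →
FBP.

## Phase retrieval

Both methods work in reduced units with χ(ν) = π|ν|²/F and return maps
in the projected-phase convention φ = (2π/λ)∫δ ≥ 0, so either feeds the
same reconstruction path.  The DC component is undefined by both
filters and set to zero mean contrast.

* CTF: the weak-object spectrum obeys Î = 2 sinχ·φ̂ − 2 cosχ·B̂; under
  the homogeneous-object coupling B = (β/δ)·(−φ) this becomes
  Î = 2(sinχ + cosχ/(δ/β))·φ̂_phys.  The inversion is Wiener-regularized,
  filt = D/(D² + reg), with a two-band reg: reg_low = 10⁻⁶ below the
  first |sinχ| maximum, reg_high = 10⁻² above.  The 1/(D + reg) form is
  unstable across D's sign changes, and band weights of 10⁻³/10⁻¹ —
  sometimes quoted as defaults — bias the absorption-coupled low band
  by ~25% at δ/β = 35 (there D² ≈ 3×10⁻³); the chosen defaults keep the
  filter's analytic contracts: unit gain within 5% where |sinχ| > 0.5,
  agreement with Paganin within 2% in the small-χ limit, and ≤5% NRMSE
  in the noiseless closed loop at F = 0.0366.
* Paganin: out = −(δ/β)/2 · ln(IFT[FT(I)/(1 + (δ/β)πν²/F)]), floored
  before the logarithm.  Exact for a homogeneous object in the small-χ
  regime and increasingly a low-pass beyond.

Fresnel-number self-calibration: the radially averaged power spectrum
of a broadband hologram carries CTF zeros at ν_m = √(mF).  The detrended
log-PSD minima are matched to orders — after a coarse grid scan of F
over ±20% of the initial value, which makes the order assignment robust
to a poor starting guess — and F is refit by least squares on
ν_m² = mF.  Flat or featureless holograms return the initial value with
a warning flag.  Recovery is within 1% at F = 0.0366 (six usable zeros)
and F = 0.188 (one zero) on noiseless phase objects.

## Reconstruction

Filtered backprojection delegates to scikit-image's `iradon` (frequency
ramp/Ram-Lak on zero-padded rows, linear-interpolation backprojection,
circle geometry).  Projection and backprojection share skimage's
integer-center convention (axis at column n//2); mixing center
conventions between a hand-rolled projector and `iradon` would smear
every feature by half a pixel over 360°, which is why the projector is
built on `radon` rather than on an independent rotation.  All 360° of
views are backprojected with uniform weight (no 180° folding).  Volumes
carry mandatory units: attenuation_per_voxel for −ln(I) sinograms
(1/vox; divide by the voxel size for 1/nm), phase_per_voxel for
retrieved phase maps.

## Stain quantification

The workflow: median-filter the projections (default 8×8, even windows
anchored to the top-left pixel of the 2×2 center block) so Fresnel
fringes cancel and the image is absorption-dominated; reconstruct
−ln(I); histogram a common ROI in the stained and unstained volumes;
take each histogram's peak (center of the maximal bin after Gaussian
smoothing of the counts, ties toward lower attenuation); subtract to
get Δμ; convert with ρa = Δμ/(2 r0 λ f2) and report mass density and
mean distance with the f2 provenance.

Median-window guidance: the first Fresnel fringe lobe spans ≈ px/√F
pixels (≈5 px at F = 0.0366), and a fully coherent edge needs a window
of about three lobes (~20 px) before overshoot drops below 1% of the
step; the 8×8 default halves it, which matches typical use where
detector blur already tempers the fringes.

Peak-location parameters must resolve the Δμ being measured: bin widths
a small fraction of Δμ with smoothing chosen so the kernel spans the
within-ROI spread.  The desk-scale recovery test uses bin 2×10⁻⁷ /vox
and σ = 150 bins against a per-voxel reconstruction noise of ≈4.5×10⁻⁵
(1/vox); because FBP noise is correlated in-plane, precision comes from
slabs of independent z-slices rather than from in-plane area alone.

## Problem sizes and what the tests show

The closed-loop recovery test simulates 32×256×256 phantoms, 180 views
over 360°, at 16 and 13.8 keV — a deliberate desk scale (the reference
scans behind the real workflow used 3000 views on 2560-pixel
detectors).  At this scale a true load of 0.012 Nd/nm³ is recovered
within 15% per energy and the two energies agree within 15%; the error
budget is dominated by spatially correlated FBP noise, not by the
estimator.  Passing these tests shows the chain is internally
consistent and unbiased at the percent level under the stated noise
model; it does not validate the homogeneous-object assumption on real
heterogeneous tissue, the unstated f2 convention of published
densities, or robustness to artifacts outside the model (drift,
scatter, polychromaticity).

## Known limitations

* Strong-phase objects (φ ≳ 1 rad) violate the linearized CTF; the
  quantification path avoids this via phase suppression, but retrieved
  phase volumes of strong objects are qualitative.
* The ring filter attenuates genuine angle-static fine structure of
  near-circularly-symmetric objects.
* Scattering-factor tables inherit Cromer–Liberman's reduced accuracy
  within a few percent of absorption edges.
* The rotation-axis estimator assumes the object (plus fringes) stays
  within the detector at all angles.
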