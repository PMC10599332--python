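"""Physical constants used package-wide.

Internal units are keV, nm and atoms/nm^3 throughout; conversions happen
only at interface boundaries.
"""

#: hc in keV*nm (12.39842 keV*Angstrom). Single source of truth for the
#: energy-wavelength conversion lambda = HC_KEV_NM / E.
HC_KEV_NM: float = 1.239842

#: Thomson scattering length (classical electron radius) in nm.
#: Kept at the two-digit value commonly quoted for stain quantification;
#: overridable via function arguments where it enters.
R0_NM: float = 2.82e-6

#: Avogadro constant in 1/mol.
N_AVOGADRO: float = 6.02214076e23

#: Conversion factor: number density in nm^-3 times A [g/mol] divided by
#: this gives mass density in g/cm^3 (1 nm^-3 = 1e21 cm^-3).
_NM3_TO_CM3_PER_MOL: float = N_AVOGADRO / 1e21
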