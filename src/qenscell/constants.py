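"""Physical constants and unit conversions.

Internal convention: energies and line widths in meV, times in ps,
lengths in Angstrom.  Translational diffusion coefficients cross the API
boundary in cm^2/s (the unit the field reports) and are converted to
Angstrom^2/ps internally.
"""

#: hbar in meV*ps
HBAR_MEV_PS = 0.6582119569

#: 1 cm^2/s expressed in Angstrom^2/ps (1e16 A^2 / 1e12 ps)
CM2S_TO_A2PS = 1.0e4

#: default water rotation radius: O-H distance, Angstrom
WATER_OH_RADIUS_A = 0.98

#: FWHM / sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # 1 / (2 sqrt(2 ln 2))


def d_cm2s_to_A2ps(d_cm2s: float) -> float:
    """Convert a translational diffusion coefficient from cm^2/s to A^2/ps."""
    return d_cm2s * CM2S_TO_A2PS
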