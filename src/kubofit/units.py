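"""Unit conventions.

Frequencies and frequency-like parameters are carried in wavenumbers
(cm^-1), times in picoseconds, and rates in ps^-1.  Inside response
functions, wavenumber quantities are converted to angular frequencies
(rad/ps) through ``TWO_PI_C``; squared Kubo amplitudes (cm^-2) convert
through ``TWO_PI_C**2``.
"""

#: speed of light in cm/ps
C_CM_PER_PS = 0.0299792458

#: 2*pi*c -- multiply a wavenumber (cm^-1) by this to get rad/ps
TWO_PI_C = 2.0 * 3.141592653589793 * C_CM_PER_PS


def wavenumber_to_angular(nu_cm: float) -> float:
    """Convert a wavenumber in cm^-1 to an angular frequency in rad/ps."""
    return nu_cm * TWO_PI_C


def angular_to_wavenumber(omega_rad_ps: float) -> float:
    """Convert an angular frequency in rad/ps to a wavenumber in cm^-1."""
    return omega_rad_ps / TWO_PI_C
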