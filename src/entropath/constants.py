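"""Physical constants and unit conversions.

Internal unit system: length in angstrom (A), time in femtosecond (fs),
mass in atomic mass units (amu), energy in kcal/mol.  In these units the
acceleration produced by a force of 1 kcal/mol/A acting on 1 amu is
``KCAL_MOL_TO_INTERNAL`` A/fs^2.
"""

# kcal/mol/A per amu -> A/fs^2
KCAL_MOL_TO_INTERNAL = 4.184e-4

# Boltzmann constant / gas constant
KB_KCAL = 0.0019872          # kcal/(mol K)
R_CAL = 1.9872               # cal/(mol K)

# spectroscopy
KCAL_PER_WAVENUMBER = 1.0 / 349.755   # kcal/mol per cm^-1
SPEED_OF_LIGHT_CM_FS = 2.99792458e-5  # cm per fs

# default simulation temperature (K)
ROOM_T = 298.15


def wavenumber_from_eigenvalue(lam: float) -> float:
    """Convert a mass-weighted Hessian eigenvalue (kcal/mol/A^2/amu) to a
    harmonic wavenumber in cm^-1.  Negative eigenvalues map to negative
    wavenumbers (imaginary modes)."""
    import numpy as np

    omega = np.sqrt(np.abs(lam) * KCAL_MOL_TO_INTERNAL)  # rad/fs
    nu = omega / (2.0 * np.pi * SPEED_OF_LIGHT_CM_FS)
    return float(np.sign(lam) * nu)
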