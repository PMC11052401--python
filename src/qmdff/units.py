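"""Unit system and physical constants.

The internal unit system follows the GROMACS convention and is internally
consistent: length nm, time ps, mass amu (g/mol), energy kJ/mol, charge e,
temperature K, angle radians.  Public interfaces accept and report dihedral
angles in degrees; converters are provided for the figure units used in the
molecular-photophysics literature (Angstrom, eV, cm^-1).
"""

import math

#: Coulomb prefactor f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
F_COULOMB = 138.935458

#: Boltzmann constant in kJ mol^-1 K^-1.
KB = 0.00831446261815324

#: 1 eV in kJ/mol.
KJ_PER_EV = 96.48533212331

#: Planck relation constant: lambda(nm) = HC_EV_NM / E(eV).
HC_EV_NM = 1239.84198

#: Internal pressure unit (kJ mol^-1 nm^-3) expressed in bar.
BAR_PER_INTERNAL = 16.6054

#: Speed of light in cm/ps, for harmonic wavenumbers.
C_CM_PER_PS = 2.99792458e-2

DEG_PER_RAD = 180.0 / math.pi
RAD_PER_DEG = math.pi / 180.0

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0


def kjmol_to_ev(e: float) -> float:
    return e / KJ_PER_EV


def ev_to_kjmol(e: float) -> float:
    return e * KJ_PER_EV


def ev_to_nm(e_ev: float) -> float:
    return HC_EV_NM / e_ev


def nm_to_ev(lam_nm: float) -> float:
    return HC_EV_NM / lam_nm


def omega_to_wavenumber(omega_rad_per_ps: float) -> float:
    """Angular frequency (rad/ps) to spectroscopic wavenumber (cm^-1)."""
    return omega_rad_per_ps / (2.0 * math.pi * C_CM_PER_PS)
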