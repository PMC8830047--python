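"""Physical constants and unit conversions pinned in one place.

Every number printed by the package traces back to this table.  Internal
computation is carried out in Hartree atomic units (hbar = m_e = e = 1);
I/O uses the spectroscopic units eV, cm^-1, fs, Angstrom and amu.
"""

#: Hartree -> eV
HARTREE_EV = 27.211386

#: cm^-1 per eV
CM_PER_EV = 8065.544

#: hbar in eV * fs  (lifetime broadening Gamma = HBAR_EV_FS / tau)
HBAR_EV_FS = 0.6582120

#: molar gas constant, J mol^-1 K^-1 (Boltzmann conformer weights)
GAS_CONSTANT_J_MOL_K = 8.314462

#: atomic mass unit in electron masses
AMU_TO_ME = 1822.888486

#: Bohr radius in Angstrom
BOHR_ANGSTROM = 0.529177210903

#: Gaussian FWHM -> standard deviation
FWHM_TO_SIGMA = 2.0 * (2.0 * 0.6931471805599453) ** 0.5  # 2*sqrt(2 ln 2) = 2.3548...


def cm1_to_hartree(omega_cm1):
    """Vibrational wavenumber (cm^-1) to angular frequency in atomic units."""
    return omega_cm1 / CM_PER_EV / HARTREE_EV


def hartree_to_ev(e):
    return e * HARTREE_EV


def ev_to_hartree(e):
    return e / HARTREE_EV


def cm1_to_ev(omega_cm1):
    return omega_cm1 / CM_PER_EV


def constants_table() -> dict:
    """All pinned constants, for debug logging and reproducibility."""
    return {
        "hartree_ev": HARTREE_EV,
        "cm_per_ev": CM_PER_EV,
        "hbar_ev_fs": HBAR_EV_FS,
        "gas_constant_J_mol_K": GAS_CONSTANT_J_MOL_K,
        "amu_to_me": AMU_TO_ME,
        "bohr_angstrom": BOHR_ANGSTROM,
    }
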