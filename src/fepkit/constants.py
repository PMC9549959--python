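"""Physical constants and unit conversions.

Internal units: energy kJ/mol, length nm, mass amu, charge e, time ps,
temperature K, pressure bar.  Reported free energies use kcal/mol.
"""

# Boltzmann constant, kJ/mol/K (CODATA, molar gas constant / 1000)
KB_KJ = 0.008314462618

# Boltzmann constant for kcal/mol reporting; fixed value for bit-exact output
KB_KCAL = 0.0019872043

# Coulomb constant k_e = 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB_KJ = 138.935458

KCAL_PER_KJ = 1.0 / 4.184
KJ_PER_KCAL = 4.184

# 1 bar * nm^3 in kJ/mol: 1e5 Pa * 1e-27 m^3 * N_A / 1000
AVOGADRO = 6.02214076e23
BAR_NM3_TO_KJ = 1.0e5 * 1.0e-27 * AVOGADRO / 1000.0

ATM_IN_BAR = 1.01325

STANDARD_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "Na": 22.990, "K": 39.098, "Ar": 39.948, "He": 4.0026,
}
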