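"""Physical constants and unit conversions.

All internal arithmetic is in Hartree atomic units (bohr, hartree,
elementary charge).  Angstrom appears only at user-facing interfaces
(XYZ files, site tables, CLI options).
"""

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903
HARTREE_TO_KCALMOL = 627.509474063

# Fermi constant of the homogeneous-electron-gas kinetic energy density,
# c_F = (3/10) (3 pi^2)^(2/3)
import math

C_FERMI = 0.3 * (3.0 * math.pi**2) ** (2.0 / 3.0)

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}
SYMBOLS = {v: k for k, v in ATOMIC_NUMBERS.items()}

# CODATA-style standard atomic weights (amu), used only for centres of
# mass and principal axes of inertia.
ATOMIC_MASSES = {
    1: 1.008, 2: 4.0026, 3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305,
    13: 26.982, 14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45, 18: 39.948,
}
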