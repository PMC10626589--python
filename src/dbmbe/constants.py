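"""Physical constants and per-element data (CODATA 2018 conversion factors)."""

# 1 Bohr in Angstrom
BOHR_IN_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_IN_ANGSTROM

# 1 Hartree in kJ/mol
HARTREE_TO_KJMOL = 2625.4996394799

# Element symbol -> nuclear charge
ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}
Z_ELEMENT = {z: sym for sym, z in ELEMENT_Z.items()}

# Covalent radii in Angstrom (Cordero et al. 2008 values for the light
# elements this package targets); used for connectivity-based fragmentation.
COVALENT_RADIUS = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
}

# Bragg-Slater radii in Angstrom, used to scale the radial quadrature and
# the Becke cell-size adjustment (H uses Becke's recommended 0.35 A).
BRAGG_RADIUS = {
    "H": 0.35, "He": 1.40, "Li": 1.45, "Be": 1.05, "B": 0.85, "C": 0.70,
    "N": 0.65, "O": 0.60, "F": 0.50, "Ne": 1.54, "Na": 1.80, "Mg": 1.50,
    "Al": 1.25, "Si": 1.10, "P": 1.00, "S": 1.00, "Cl": 1.00, "Ar": 1.88,
}
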