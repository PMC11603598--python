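"""Physical constants and unit conversions (CODATA 2018)."""

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

#: proton mass in electron masses
PROTON_MASS = 1836.15267343

KCAL_PER_HARTREE = 627.5094740631
CM1_PER_HARTREE = 219474.6313632

ATOMIC_NUMBERS = {
    "H": 1, "He": 2,
    "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
    "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17,
    "Ar": 18,
}

ELEMENT_SYMBOLS = {z: s for s, z in ATOMIC_NUMBERS.items()}
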