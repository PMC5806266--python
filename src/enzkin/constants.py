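"""Physical constants and reference tables used throughout the package.

Every numeric constant the models depend on lives here so tests can pin
exact values and no module hard-codes its own copy.
"""

#: Gas constant, J mol^-1 K^-1.
R = 8.314

#: Boltzmann constant over reduced Planck constant, K^-1 s^-1 (Eyring prefactor).
KB_OVER_HBAR = 2.08366e10

#: Thermochemical calorie, J.
CAL_TO_J = 4.184
KCAL_TO_J = 4184.0

#: Celsius -> Kelvin offset.
CELSIUS_OFFSET = 273.15

#: Average mass of one water molecule, Da (added once per peptide chain).
WATER_AVG_MASS = 18.01524

#: Default Arrhenius pre-exponential factor for barrier estimates, s^-1.
DEFAULT_PREEXPONENTIAL = 6.0e12

#: Default reference temperature for Arrhenius decompositions, K (40 degC assay).
DEFAULT_T0 = 313.15

#: ExPASy-style average residue masses, Da (residue = amino acid - water).
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

STANDARD_RESIDUES = frozenset(AVERAGE_RESIDUE_MASS)

# Ionizable-group pKa tables for isoelectric-point calculation.
# Keys: side chains D,E,C,Y,H,K,R plus chain termini.
PKA_TABLES = {
    # Bjellqvist values (the set behind the ExPASy tools), generic termini.
    "bjellqvist": {
        "Nterm": 7.50, "Cterm": 3.55,
        "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,
        "H": 5.98, "K": 10.00, "R": 12.00,
    },
    # EMBOSS iep defaults.
    "emboss": {
        "Nterm": 8.60, "Cterm": 3.60,
        "D": 3.90, "E": 4.10, "C": 8.50, "Y": 10.10,
        "H": 6.50, "K": 10.80, "R": 12.50,
    },
}

DEFAULT_PKA_TABLE = "bjellqvist"

#: Groups carrying positive charge when protonated.
POSITIVE_GROUPS = ("Nterm", "H", "K", "R")
#: Groups carrying negative charge when deprotonated.
NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")


def celsius_to_kelvin(t_c):
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k):
    return t_k - CELSIUS_OFFSET
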