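"""Independent elemental-composition mass oracle for tests.

Computes peptide and modification masses from residue chemical formulas and
atomic monoisotopic masses, sharing no code or data tables with the package's
mass path (which goes through pyteomics residue masses).
"""

from __future__ import annotations

import re

ATOM = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

# residue (i.e. amino acid minus water) formulas
RESIDUE_FORMULA = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}

MOD_FORMULA = {
    # net atom changes of each modification
    "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    "hydroxylation": {"O": 1},
    "deamidation": {"O": 1, "N": -1, "H": -1},
    "ammonia_loss": {"N": -1, "H": -3},
    "hexose": {"C": 6, "H": 10, "O": 5},
}

PROTON = 1.00727646688


def formula_mass(formula: str) -> float:
    total = 0.0
    for element, count in re.findall(r"([A-Z])(\d*)", formula):
        total += ATOM[element] * (int(count) if count else 1)
    return total


def mod_delta(name: str) -> float:
    return sum(ATOM[el] * n for el, n in MOD_FORMULA[name].items())


def peptide_mass(sequence: str, n_carbamidomethyl: int = 0, extra_deltas=()) -> float:
    total = sum(formula_mass(RESIDUE_FORMULA[aa]) for aa in sequence)
    total += formula_mass("H2O")
    total += n_carbamidomethyl * mod_delta("carbamidomethyl")
    total += sum(extra_deltas)
    return total


def mz(neutral_mass: float, charge: int) -> float:
    return (neutral_mass + charge * PROTON) / charge
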