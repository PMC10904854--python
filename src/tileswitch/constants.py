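"""Physical constants and per-residue tables shared across the package.

Units are fixed package-wide: Å, Da, elementary charge, kcal/mol.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

#: Electrostatic conversion factor, kcal·Å/mol/e².
COULOMB_CONSTANT = 332.0637

#: Mass of a proton, Da (used for m/z).
PROTON_MASS = 1.007276

#: Average mass of water, Da.
WATER_MASS = 18.0153

#: Avogadro's number scaled so that molarity × volume[Å³] gives molecule counts.
MOLECULES_PER_MOLAR_A3 = 6.02214076e-4

#: Average residue (not free amino-acid) masses, Da.
RESIDUE_AVERAGE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

STANDARD_AMINO_ACIDS = frozenset(RESIDUE_AVERAGE_MASS)

#: Hydrophobic-and-bulky residue set used for composition analysis.  With this
#: set the coreMYC segment (c-MYC 101-150) is exactly half hydrophobic (25/50).
HYDROPHOBIC_SET = frozenset("ACFILMVW")

#: Positively / negatively charged residues at pH 7 (formal charges).
POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

#: N-terminal modification mass deltas, Da.
NTERM_DELTAS = {"free": 0.0, "acetyl": 42.0367, "formyl": 28.0101}
#: C-terminal modification mass deltas, Da (amide: NH2 replaces OH).
CTERM_DELTAS = {"free": 0.0, "amide": -0.9847}


def _data_path(name: str):
    return importlib.resources.files("tileswitch.data").joinpath(name)


def load_hydrophobicity_scale(name: str = "miyazawa") -> dict[str, float]:
    """Return a per-residue hydrophobicity score table by scale name."""
    table = pd.read_csv(_data_path("hydrophobicity_scales.tsv"), sep="\t", comment="#")
    if name not in table.columns:
        available = [c for c in table.columns if c != "residue"]
        raise KeyError(f"unknown hydrophobicity scale {name!r}; available: {available}")
    return dict(zip(table["residue"], table[name].astype(float)))


def cmyc_sequence_path():
    """Path to the shipped canonical 439-residue human c-MYC FASTA."""
    return _data_path("cmyc_p01106.fasta")


def default_param_table_path():
    """Path to the shipped one-bead-per-residue parameter table."""
    return _data_path("bead_params.tsv")


def heavy_param_table_path():
    """Path to the shipped minimal heavy-atom (backbone+CB) parameter table."""
    return _data_path("heavy_minimal_params.tsv")
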