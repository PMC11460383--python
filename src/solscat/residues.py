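"""Residue topology dictionaries: heavy atom -> atom-group label.

Maps (residue name, atom name) of standard biopolymer residues to the
implicit-hydrogen group labels of the form-factor table.  Covers the 20
amino acids, DNA/RNA nucleotides, water and pyranose sugars (for
cyclodextrins and common glycans).  Hydrogen counts follow standard
protonation at neutral pH: carboxylates deprotonated, LYS/ARG/N-terminus
protonated, HIS neutral (NE2-H tautomer).
"""

from __future__ import annotations

__all__ = ["lookup_group_label", "PROTEIN_RESIDUES", "NUCLEIC_RESIDUES"]

# ---------------------------------------------------------------- proteins

_BACKBONE = {"N": "NH", "CA": "CH", "C": "C", "O": "O", "OXT": "O"}

_SIDECHAINS: dict[str, dict[str, str]] = {
    "ALA": {"CB": "CH3"},
    "ARG": {"CB": "CH2", "CG": "CH2", "CD": "CH2", "NE": "NH", "CZ": "C",
            "NH1": "NH2", "NH2": "NH2"},
    "ASN": {"CB": "CH2", "CG": "C", "OD1": "O", "ND2": "NH2"},
    "ASP": {"CB": "CH2", "CG": "C", "OD1": "O", "OD2": "O"},
    "CYS": {"CB": "CH2", "SG": "SH"},
    "GLN": {"CB": "CH2", "CG": "CH2", "CD": "C", "OE1": "O", "NE2": "NH2"},
    "GLU": {"CB": "CH2", "CG": "CH2", "CD": "C", "OE1": "O", "OE2": "O"},
    "GLY": {},
    "HIS": {"CB": "CH2", "CG": "C", "ND1": "N", "CD2": "CH", "CE1": "CH",
            "NE2": "NH"},
    "ILE": {"CB": "CH", "CG1": "CH2", "CG2": "CH3", "CD1": "CH3"},
    "LEU": {"CB": "CH2", "CG": "CH", "CD1": "CH3", "CD2": "CH3"},
    "LYS": {"CB": "CH2", "CG": "CH2", "CD": "CH2", "CE": "CH2", "NZ": "NH3"},
    "MET": {"CB": "CH2", "CG": "CH2", "SD": "S", "CE": "CH3"},
    "PHE": {"CB": "CH2", "CG": "C", "CD1": "CH", "CD2": "CH", "CE1": "CH",
            "CE2": "CH", "CZ": "CH"},
    "PRO": {"CB": "CH2", "CG": "CH2", "CD": "CH2"},
    "SER": {"CB": "CH2", "OG": "OH"},
    "THR": {"CB": "CH", "OG1": "OH", "CG2": "CH3"},
    "TRP": {"CB": "CH2", "CG": "C", "CD1": "CH", "CD2": "C", "NE1": "NH",
            "CE2": "C", "CE3": "CH", "CZ2": "CH", "CZ3": "CH", "CH2": "CH"},
    "TYR": {"CB": "CH2", "CG": "C", "CD1": "CH", "CD2": "CH", "CE1": "CH",
            "CE2": "CH", "CZ": "C", "OH": "OH"},
    "VAL": {"CB": "CH", "CG1": "CH3", "CG2": "CH3"},
}

PROTEIN_RESIDUES: dict[str, dict[str, str]] = {}
for _res, _side in _SIDECHAINS.items():
    d = dict(_BACKBONE)
    d.update(_side)
    if _res == "GLY":
        d["CA"] = "CH2"
    if _res == "PRO":
        d["N"] = "N"
    PROTEIN_RESIDUES[_res] = d

# --------------------------------------------------------------- nucleics

# sugar-phosphate; C2'/O2' entries overridden per DNA/RNA below
_SUGAR_PHOSPHATE = {
    "P": "P", "OP1": "O", "OP2": "O", "OP3": "O", "O1P": "O", "O2P": "O",
    "O3P": "O", "O5'": "O", "C5'": "CH2", "C4'": "CH", "O4'": "O",
    "C3'": "CH", "O3'": "O", "C1'": "CH",
}

_BASES = {
    "A": {"N9": "N", "C8": "CH", "N7": "N", "C5": "C", "C6": "C",
          "N6": "NH2", "N1": "N", "C2": "CH", "N3": "N", "C4": "C"},
    "G": {"N9": "N", "C8": "CH", "N7": "N", "C5": "C", "C6": "C", "O6": "O",
          "N1": "NH", "C2": "C", "N2": "NH2", "N3": "N", "C4": "C"},
    "C": {"N1": "N", "C2": "C", "O2": "O", "N3": "N", "C4": "C",
          "N4": "NH2", "C5": "CH", "C6": "CH"},
    "T": {"N1": "N", "C2": "C", "O2": "O", "N3": "NH", "C4": "C", "O4": "O",
          "C5": "C", "C7": "CH3", "C5M": "CH3", "C6": "CH"},
    "U": {"N1": "N", "C2": "C", "O2": "O", "N3": "NH", "C4": "C", "O4": "O",
          "C5": "CH", "C6": "CH"},
}

NUCLEIC_RESIDUES: dict[str, dict[str, str]] = {}
for _name, _base, _is_dna in [
    ("DA", "A", True), ("DG", "G", True), ("DC", "C", True), ("DT", "T", True),
    ("A", "A", False), ("G", "G", False), ("C", "C", False), ("U", "U", False),
]:
    d = dict(_SUGAR_PHOSPHATE)
    d.update(_BASES[_base])
    if _is_dna:
        d["C2'"] = "CH2"
    else:
        d["C2'"] = "CH"
        d["O2'"] = "OH"
    NUCLEIC_RESIDUES[_name] = d

# ----------------------------------------------------- sugars and water

# pyranose ring (glucose and relatives); glycosidic O4/O5 bare, others OH
_PYRANOSE = {
    "C1": "CH", "C2": "CH", "C3": "CH", "C4": "CH", "C5": "CH", "C6": "CH2",
    "O1": "OH", "O2": "OH", "O3": "OH", "O4": "O", "O5": "O", "O6": "OH",
}
SUGAR_RESIDUES = {name: dict(_PYRANOSE) for name in
                  ("GLC", "BGC", "MGL", "GAL", "MAN", "BMA", "NAG", "NDG")}

WATER_RESIDUES = {name: {"O": "H2O", "OW": "H2O"} for name in
                  ("HOH", "WAT", "DOD", "H2O")}

_ALL: dict[str, dict[str, str]] = {}
_ALL.update(PROTEIN_RESIDUES)
_ALL.update(NUCLEIC_RESIDUES)
_ALL.update(SUGAR_RESIDUES)
_ALL.update(WATER_RESIDUES)


def is_known_residue(res_name: str) -> bool:
    return res_name.strip().upper() in _ALL


def lookup_group_label(res_name: str, atom_name: str) -> str | None:
    """Group label for a heavy atom of a known residue, else None."""
    res = _ALL.get(res_name.strip().upper())
    if res is None:
        return None
    return res.get(atom_name.strip().upper().replace("*", "'"))
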