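"""Static chemistry tables used by the atomic residue descriptor.

All values are standard reference data: atomic masses (u), van der Waals
radii (Å, Bondi), per-heavy-atom bonded-hydrogen counts and ring membership
for the 20 standard amino acids, and theoretical maximum solvent
accessibilities (Å^2, Tien et al. 2013) used to compute relative SASA.
"""

from __future__ import annotations

# Heavy-atom element alphabet used by the one-hot channel.
ELEMENT_CLASSES = ("C", "N", "O", "S", "OTHER")

ATOMIC_MASS = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "CA": 40.078, "MN": 54.938,
}
DEFAULT_MASS = 12.011

VDW_RADIUS = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98, "FE": 2.00, "ZN": 1.39,
    "MG": 1.73, "CA": 2.00, "MN": 2.00,
}
DEFAULT_VDW = 1.70

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Heavy atoms per residue (backbone + side chain), PDB atom names.
SIDECHAIN_ATOMS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

# Bonded hydrogens on each heavy atom (neutral pH protonation, termini ignored).
_BB_H = {"N": 1, "CA": 1, "C": 0, "O": 0}
_SC_H = {
    "ALA": {"CB": 3},
    "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "CZ": 0, "NH1": 2, "NH2": 2},
    "ASN": {"CB": 2, "CG": 0, "OD1": 0, "ND2": 2},
    "ASP": {"CB": 2, "CG": 0, "OD1": 0, "OD2": 0},
    "CYS": {"CB": 2, "SG": 1},
    "GLN": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "NE2": 2},
    "GLU": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "OE2": 0},
    "GLY": {},
    "HIS": {"CB": 2, "CG": 0, "ND1": 1, "CD2": 1, "CE1": 1, "NE2": 0},
    "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "MET": {"CB": 2, "CG": 2, "SD": 0, "CE": 3},
    "PHE": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "PRO": {"CB": 2, "CG": 2, "CD": 2},
    "SER": {"CB": 2, "OG": 1},
    "THR": {"CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 0, "NE1": 1, "CE2": 0,
            "CE3": 1, "CZ2": 1, "CZ3": 1, "CH2": 1},
    "TYR": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1,
            "CZ": 0, "OH": 1},
    "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
}

# Ring-member heavy atoms (aromatic rings plus the proline pyrrolidine).
_RING_ATOMS = {
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"N", "CA", "CB", "CG", "CD"},
}

# Theoretical maximum accessible surface area per residue (Tien et al. 2013).
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_MAX_SASA = 200.0

CHARGED_AA = "DEHKR"

# Fixed amino-acid column order used for PSSM matrices (PSI-BLAST order).
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


def element_class(element: str) -> str:
    """Map an element symbol onto the 5-way one-hot alphabet."""
    e = element.upper()
    return e if e in ("C", "N", "O", "S") else "OTHER"


def hydrogen_count(resname: str, atom_name: str) -> int:
    if atom_name in _BB_H:
        return _BB_H[atom_name]
    return _SC_H.get(resname, {}).get(atom_name, 0)


def in_ring(resname: str, atom_name: str) -> bool:
    return atom_name in _RING_ATOMS.get(resname, set())


def heavy_atoms(resname: str) -> list[str]:
    """Full heavy-atom name list (backbone then side chain) for a residue."""
    return list(BACKBONE_ATOMS) + SIDECHAIN_ATOMS.get(resname, [])
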