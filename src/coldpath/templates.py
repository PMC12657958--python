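"""Residue knowledge: template atoms/bonds, named torsions, aromatic rings.

Template data (atom sets, intra-residue bonds, idealised coordinates with
hydrogens) come from the Chemical Component Dictionary bundled with biotite,
so no network access is ever needed.  On top of that this module defines the
conventional torsion nomenclature (phi/psi/omega/chi_n), the ring systems
treated as rigid and as aromatic, and the sidechain symmetry rules used when
reconciling two crystallographic end states.
"""

from __future__ import annotations

from functools import lru_cache

import gemmi
import numpy as np

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Atoms considered part of the polypeptide main chain.
MAIN_CHAIN_ATOMS = {
    "N", "CA", "C", "O", "OXT",
    "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT",
}

#: Aromatic ring membership by residue type.  TRP's fused bicycle is a single
#: rigid aromatic unit, so it carries one ring id.
AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2")],
}

#: Sidechain chi torsions keyed by central-bond atom names (standard order).
CHI_BONDS = {
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ")],
    "ASN": [("CA", "CB"), ("CB", "CG")],
    "ASP": [("CA", "CB"), ("CB", "CG")],
    "CYS": [("CA", "CB")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD")],
    "HIS": [("CA", "CB"), ("CB", "CG")],
    "ILE": [("CA", "CB"), ("CB", "CG1")],
    "LEU": [("CA", "CB"), ("CB", "CG")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD")],
    "PHE": [("CA", "CB"), ("CB", "CG")],
    "PRO": [("CA", "CB"), ("CB", "CG")],
    "SER": [("CA", "CB")],
    "THR": [("CA", "CB")],
    "TRP": [("CA", "CB"), ("CB", "CG")],
    "TYR": [("CA", "CB"), ("CB", "CG")],
    "VAL": [("CA", "CB")],
}

#: Conventional chi quadruples (atom names); used when present.
CHI_QUADS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
            ("CD", "NE", "CZ", "NH1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

#: Terminal 180 deg-symmetric torsion per residue type: chi index (1-based).
#: "always" residues have chemically indistinguishable/symmetric terminal
#: groups; "low_res" residues only look symmetric in poor electron density.
SYMMETRIC_CHI_ALWAYS = {"PHE": 2, "TYR": 2, "ASP": 2, "GLU": 3, "ARG": 5}
SYMMETRIC_CHI_LOW_RES = {"ASN": 2, "GLN": 3, "HIS": 2}
LOW_RES_THRESHOLD = 2.4  # Angstrom; symmetry rule extends to ASN/GLN/HIS above


@lru_cache(maxsize=None)
def template(res_name: str):
    """CCD template for a residue: (atom_names, elements, coords, bonds).

    ``bonds`` is a frozenset of frozensets of atom names.
    """
    import biotite.structure.info as info

    res_name = res_name.upper()
    if res_name not in AMINO_ACIDS:
        raise KeyError(f"unknown residue type {res_name!r}")
    arr = info.residue(res_name)
    names = tuple(arr.atom_name)
    elements = tuple(e.capitalize() for e in arr.element)
    coords = np.array(arr.coord, dtype=float)
    bonds = frozenset(
        frozenset(pair) for pair in info.bonds_in_residue(res_name)
    )
    return names, elements, coords, bonds


@lru_cache(maxsize=None)
def element_info(element: str) -> tuple[int, float]:
    """(atomic number, van der Waals radius in A) for an element symbol."""
    el = gemmi.Element(element)
    z = el.atomic_number
    if z <= 0:
        raise ValueError(f"unresolvable element symbol {element!r}")
    return z, float(el.vdw_r)


def is_hydrogen(element: str) -> bool:
    return element.upper() in ("H", "D")


def chi_name_for_bond(res_name: str, name_a: str, name_b: str) -> str | None:
    """Conventional chi label for an intra-residue central bond, if any."""
    bonds = CHI_BONDS.get(res_name.upper(), [])
    key = frozenset((name_a, name_b))
    for k, pair in enumerate(bonds):
        if frozenset(pair) == key:
            return f"chi{k + 1}"
    return None


ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
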