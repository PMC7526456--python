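"""Chemical reference data: amino-acid codes, van-der-Waals radius tables,
ideal residue geometry (from the chemical component dictionary shipped with
biotite), side-chain torsion (chi) definitions and most-common rotamer
defaults, and per-residue bond graphs.

Radius tables are element-keyed.  Two published sets are embedded:

``bondi``
    Bondi (1964) element radii as commonly applied to proteins
    (C 1.70, N 1.55, O 1.52, S 1.80 A).  Default.
``chothia``
    Chothia (1975)-style protein set with a larger carbon
    (C 1.87, N 1.65, O 1.40, S 1.85 A).

The buried/exposed annotation downstream depends on the *ratio* of a
side chain's area to its fully exposed reference, so the choice of table
moves absolute areas but barely moves the in/out calls.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA3 = frozenset(THREE_TO_ONE)
STANDARD_AA1 = frozenset(ONE_TO_THREE)

#: Backbone heavy-atom names of an amino acid.  OXT (the C-terminal
#: carboxylate oxygen) is counted as backbone, like the peptide O.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

RADIUS_TABLES: dict[str, dict[str, float]] = {
    "bondi": {
        "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
        "S": 1.80, "P": 1.80, "SE": 1.90, "F": 1.47,
    },
    "chothia": {
        "H": 1.00, "C": 1.87, "N": 1.65, "O": 1.40,
        "S": 1.85, "P": 1.90, "SE": 1.90, "F": 1.47,
    },
}
DEFAULT_RADIUS_TABLE = "bondi"

#: Elements whose surface counts as apolar in the area decomposition.
APOLAR_ELEMENTS = frozenset({"C", "S"})

# Side-chain chi dihedral definitions (atom name quadruples), standard
# IUPAC order.  Proline's ring is kept rigid (no free chi).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "PRO": [],
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

# One embedded most-common rotamer per residue type (degrees), used when a
# template residue offers no chi to copy.  Values follow the dominant bins
# of backbone-independent rotamer statistics.
CHI_DEFAULTS: dict[str, list[float]] = {
    "ALA": [], "GLY": [], "PRO": [],
    "SER": [64.0], "CYS": [-65.0], "THR": [62.0], "VAL": [175.0],
    "ILE": [-65.0, 170.0], "LEU": [-65.0, 175.0],
    "ASP": [-70.0, -15.0], "ASN": [-65.0, -40.0],
    "HIS": [-65.0, -75.0], "PHE": [-65.0, 95.0],
    "TYR": [-65.0, 95.0], "TRP": [-65.0, 95.0],
    "MET": [-65.0, 180.0, 75.0],
    "GLU": [-65.0, 180.0, -10.0], "GLN": [-65.0, 180.0, -25.0],
    "LYS": [-65.0, 180.0, 180.0, 180.0],
    "ARG": [-65.0, 180.0, 180.0, 180.0],
}


@lru_cache(maxsize=None)
def residue_template(resname: str):
    """Ideal heavy-atom geometry of a standard residue.

    Returns ``(names, elements, coords, bonds)`` where *bonds* is a frozenset
    of name pairs.  Hydrogens and the terminal OXT are stripped; geometry
    comes from the chemical component dictionary bundled with biotite.
    """
    import biotite.structure.info as struc_info

    resname = resname.upper()
    if resname not in STANDARD_AA3:
        raise KeyError(f"not a standard amino acid: {resname!r}")
    arr = struc_info.residue(resname)
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    idx = np.where(keep)[0]
    names = tuple(arr.atom_name[idx])
    elements = tuple(arr.element[idx])
    coords = arr.coord[idx].astype(float)
    name_of = {orig: arr.atom_name[orig] for orig in idx}
    bonds = set()
    for i, j, _ in arr.bonds.as_array():
        if i in name_of and j in name_of:
            bonds.add(frozenset((name_of[i], name_of[j])))
    return names, elements, coords, frozenset(bonds)


@lru_cache(maxsize=None)
def sidechain_atom_names(resname: str) -> tuple[str, ...]:
    names, _, _, _ = residue_template(resname)
    return tuple(n for n in names if n not in BACKBONE_ATOMS)


@lru_cache(maxsize=None)
def chi_moved_atoms(resname: str) -> tuple[tuple[str, ...], ...]:
    """For each chi of *resname*, the atom names moved by rotating that chi.

    Derived from the residue bond graph: everything downstream of the
    rotated bond, excluding the two axis atoms.
    """
    names, _, _, bonds = residue_template(resname)
    adj: dict[str, set[str]] = {n: set() for n in names}
    for pair in bonds:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)
    moved_all = []
    for _, b, c, _ in CHI_ATOMS[resname]:
        seen = {b, c}
        stack = [c]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        moved_all.append(tuple(sorted(seen - {b, c})))
    return tuple(moved_all)
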