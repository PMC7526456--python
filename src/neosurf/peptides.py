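"""Peptide construction primitives.

Residue geometry is taken from the ideal coordinates of the chemical
component dictionary (via :func:`neosurf.chem.residue_template`) and placed
onto an arbitrary backbone frame by superposing the template's N/CA/C onto
the target N/CA/C.  Side-chain conformation is then set through the
standard chi dihedrals.  An extended-backbone builder provides both the
Gly-X-Gly reference tripeptides used by the exposure annotation and ad hoc
peptides for tests.
"""

from __future__ import annotations

import numpy as np

from ._geom import dihedral, place_atom, rotate_about_bond
from .chem import (
    BACKBONE_ATOMS,
    CHI_ATOMS,
    CHI_DEFAULTS,
    ONE_TO_THREE,
    residue_template,
    chi_moved_atoms,
)
from .structure import Atom, Residue, Structure

# Engh-Huber-style ideal backbone internal coordinates
_BB = {
    "N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
    "N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.8,
}


def _superpose_3pt(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) mapping the 3-point set src onto dst (least squares)."""
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dc - R @ sc
    return R, t


def ideal_residue(resname: str) -> Residue:
    """A free-standing residue with ideal heavy-atom geometry."""
    names, elements, coords, _ = residue_template(resname)
    atoms = [Atom(n, e, c.copy(), is_backbone=n in BACKBONE_ATOMS)
             for n, e, c in zip(names, elements, coords)]
    return Residue(resname, "1", atoms)


def get_chi(res: Residue) -> list[float]:
    """Measure the chi dihedrals present in *res* (degrees)."""
    out = []
    for quad in CHI_ATOMS.get(res.name, []):
        if all(res.has_atom(n) for n in quad):
            out.append(dihedral(*(res.atom(n).coords for n in quad)))
        else:
            break
    return out


def set_chi(res: Residue, chi_index: int, value: float) -> None:
    """Rotate the side chain of *res* so that chi ``chi_index`` equals *value*."""
    quad = CHI_ATOMS[res.name][chi_index]
    a, b, c, d = (res.atom(n).coords for n in quad)
    current = dihedral(a, b, c, d)
    delta = value - current
    moved_names = chi_moved_atoms(res.name)[chi_index]
    # right-handed rotation about b->c decreases the measured dihedral,
    # so rotate the downstream atoms by -delta
    axis = c - b
    for atom in res.atoms:
        if atom.name in moved_names:
            atom.coords = rotate_about_bond(atom.coords[None, :], b, axis, -delta)[0]


def place_side_chain(backbone: dict[str, np.ndarray], target_type: str,
                     chi_source: Residue | None = None) -> list[Atom]:
    """Build side-chain heavy atoms (CB onward) for *target_type* on a backbone frame.

    *backbone* maps "N", "CA", "C" to coordinates.  Chi angles are copied
    from *chi_source* where the torsion tree is shared (matched by chi
    index), otherwise the embedded most-common rotamer is used.

    Returns the new atoms only; backbone atoms are not touched.
    """
    for key in ("N", "CA", "C"):
        if key not in backbone:
            raise ValueError(f"backbone atom {key} missing")
    resname = ONE_TO_THREE.get(target_type, target_type).upper()
    res = ideal_residue(resname)
    src = np.array([res.atom(n).coords for n in ("N", "CA", "C")])
    dst = np.array([backbone[n] for n in ("N", "CA", "C")])
    R, t = _superpose_3pt(src, dst)
    for atom in res.atoms:
        atom.coords = R @ atom.coords + t

    n_chi = len(CHI_ATOMS[resname])
    if n_chi:
        source_chis = get_chi(chi_source) if chi_source is not None else []
        defaults = CHI_DEFAULTS[resname]
        for i in range(n_chi):
            value = source_chis[i] if i < len(source_chis) else defaults[i]
            set_chi(res, i, value)
    return [a for a in res.atoms if a.name not in BACKBONE_ATOMS]


def build_extended_peptide(sequence: str, *, phi: float = -139.0, psi: float = 135.0,
                           omega: float = 180.0, chain_id: str = "A",
                           structure_id: str = "") -> Structure:
    """Build an ideal-geometry peptide in an extended (beta-like) conformation.

    Backbone is generated residue by residue with NeRF; side chains are
    placed in their default rotamer.  Used for the fully exposed Gly-X-Gly
    reference areas and for small test fixtures.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BB["N_CA"], 0.0, 0.0])
    ang = np.radians(180.0 - _BB["N_CA_C"])
    c0 = ca0 + _BB["CA_C"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for _ in sequence[1:]:
        prev = bb[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"],
                       _BB["C_N"], _BB["CA_C_N"], psi)
        ca = place_atom(prev["CA"], prev["C"], n,
                        _BB["N_CA"], _BB["C_N_CA"], omega)
        c = place_atom(prev["C"], n, ca, _BB["CA_C"], _BB["N_CA_C"], phi)
        bb.append({"N": n, "CA": ca, "C": c})

    residues = []
    for i, one in enumerate(sequence):
        resname = ONE_TO_THREE[one]
        frame = bb[i]
        if i + 1 < len(bb):
            psi_i = dihedral(frame["N"], frame["CA"], frame["C"], bb[i + 1]["N"])
        else:
            psi_i = psi
        o = place_atom(frame["N"], frame["CA"], frame["C"],
                       _BB["C_O"], _BB["CA_C_O"], psi_i + 180.0)
        atoms = [Atom("N", "N", frame["N"], is_backbone=True),
                 Atom("CA", "C", frame["CA"], is_backbone=True),
                 Atom("C", "C", frame["C"], is_backbone=True),
                 Atom("O", "O", o, is_backbone=True)]
        atoms.extend(place_side_chain(frame, one))
        residues.append(Residue(resname, str(i + 1), atoms))
    return Structure({chain_id: residues}, id=structure_id)
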