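"""Atomic structure container and PDB input/output.

The in-memory model is deliberately small: :class:`Atom`, :class:`Residue`
and :class:`Structure` carry exactly what the surface-area and modeling
stages need — coordinates, van-der-Waals radii, a backbone flag and chain
roles (which chain is the presented peptide, which the MHC heavy chain).
Parsing of the fixed-width PDB format is delegated to gemmi; this module
adds the policy layer: altloc resolution by occupancy, removal of waters,
hydrogens and non-peptide heteroatoms, and chain-role detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .chem import (
    BACKBONE_ATOMS,
    DEFAULT_RADIUS_TABLE,
    RADIUS_TABLES,
    STANDARD_AA3,
    THREE_TO_ONE,
)


class PDBError(ValueError):
    """Problem reading or writing PDB-format content."""


class PDBParseError(PDBError):
    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyStructureError(PDBError):
    """No atoms survived parsing/filtering."""


@dataclass
class Atom:
    """A heavy atom with an assigned van-der-Waals radius.

    ``radius`` is 0.0 until :func:`assign_radii` (or a builder) sets it;
    SASA computation refuses unassigned radii.
    """

    name: str
    element: str
    coords: np.ndarray
    radius: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    is_backbone: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    name: str                     # 3-letter code
    seq_id: str                   # author numbering + insertion code, e.g. "42" or "42A"
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name} {self.seq_id}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, [a.copy() for a in self.atoms])


@dataclass
class Structure:
    """Chains of residues plus chain-role annotations.

    ``peptide_chain`` names the chain holding the presented epitope;
    ``mhc_chain`` the MHC heavy chain that forms the groove.  Either may be
    None for generic structures (e.g. atom clouds used as SASA fixtures).
    """

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    id: str = ""
    peptide_chain: str | None = None
    mhc_chain: str | None = None

    def __post_init__(self):
        if self.peptide_chain is not None:
            if self.peptide_chain not in self.chains:
                raise ValueError(f"peptide_chain {self.peptide_chain!r} not present")
            n = len(self.chains[self.peptide_chain])
            if not 8 <= n <= 10:
                raise ValueError(
                    f"peptide_chain {self.peptide_chain!r} has {n} residues, "
                    "expected 8-10")

    def atoms(self, chain: str | None = None):
        chains = [chain] if chain is not None else list(self.chains)
        for cid in chains:
            for res in self.chains[cid]:
                yield from res.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coords(self, chain: str | None = None) -> np.ndarray:
        pts = [a.coords for a in self.atoms(chain)]
        return np.array(pts) if pts else np.empty((0, 3))

    def sequence(self, chain: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain])

    def ca_coords(self, chain: str) -> np.ndarray:
        return np.array([r.atom("CA").coords for r in self.chains[chain]])

    def copy(self) -> "Structure":
        return Structure(
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
            id=self.id, peptide_chain=self.peptide_chain, mhc_chain=self.mhc_chain)


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _validate_atom_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PDBParseError("ATOM/HETATM record shorter than 54 columns", lineno)
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"unparseable {what} coordinate {fieldtxt!r}", lineno) from None


def read_pdb(text: str, *, keep_hydrogens: bool = False,
             peptide_chain: str | None = None,
             mhc_chain: str | None = None,
             structure_id: str = "",
             detect_roles: bool = True) -> Structure:
    """Parse PDB-format *text* into a :class:`Structure`.

    Policy applied on top of the raw records: per altloc group only the
    highest-occupancy conformer is retained (ties broken by alphabetically
    first altloc); waters and non-amino-acid HETATM residues are dropped;
    hydrogens are dropped unless *keep_hydrogens*.  Chains keep file order.

    When *detect_roles* and no explicit chains are given, the peptide chain
    is auto-detected as the shortest protein chain of 8-10 residues and the
    MHC heavy chain as the longest chain.
    """
    if "ATOM" not in text and "HETATM" not in text:
        raise EmptyStructureError("no ATOM records in input")
    _validate_atom_lines(text)
    try:
        gs = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(exc)) from exc
    if len(gs) == 0:
        raise EmptyStructureError("no model in input")

    model = gs[0]
    chains: dict[str, list[Residue]] = {}
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            is_het = gres.het_flag == "H"
            if gres.name in _WATER_NAMES:
                continue
            if is_het and gres.name not in STANDARD_AA3:
                continue
            seq_id = f"{gres.seqid.num}{gres.seqid.icode.strip()}"
            # altloc resolution: among *lettered* conformers of one atom
            # name keep the highest occupancy (ties: first letter); atoms
            # without an altloc are sole conformers and always kept
            def _alt(ga):
                return ga.altloc.replace("\x00", "").strip()

            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                if not keep_hydrogens and ga.element.name in ("H", "D"):
                    continue
                if not _alt(ga):
                    continue
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ or (
                        ga.occ == prev.occ and _alt(ga) < _alt(prev)):
                    best[ga.name] = ga
            atoms = []
            for ga in gres:  # file atom order preserved
                if not keep_hydrogens and ga.element.name in ("H", "D"):
                    continue
                if _alt(ga) and best[ga.name] is not ga:
                    continue
                atoms.append(Atom(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=_alt(ga),
                    is_backbone=(gres.name in STANDARD_AA3 and ga.name in BACKBONE_ATOMS),
                ))
            if atoms:
                residues.append(Residue(gres.name, seq_id, atoms))
        if residues:
            chains[gchain.name] = residues
    if not chains:
        raise EmptyStructureError("no atoms survived filtering")

    if detect_roles and len(chains) > 1:
        protein_chains = [
            (cid, len(res)) for cid, res in chains.items()
            if all(r.name in STANDARD_AA3 for r in res)]
        if peptide_chain is None:
            candidates = [c for c in protein_chains if 8 <= c[1] <= 10]
            if candidates:
                peptide_chain = min(candidates, key=lambda c: c[1])[0]
        if peptide_chain is not None and mhc_chain is None:
            others = [c for c in protein_chains if c[0] != peptide_chain]
            if others:
                mhc_chain = max(others, key=lambda c: c[1])[0]
            else:
                # no other protein chain: fall back to the largest chain by
                # atom count (e.g. a pseudo-atom groove scaffold)
                rest = [(cid, sum(len(r.atoms) for r in res))
                        for cid, res in chains.items() if cid != peptide_chain]
                if rest:
                    mhc_chain = max(rest, key=lambda c: c[1])[0]
    return Structure(chains, id=structure_id, peptide_chain=peptide_chain,
                     mhc_chain=mhc_chain)


def write_pdb(s: Structure) -> str:
    """Serialize to fixed-width ATOM records, one TER per chain."""
    if not s.chains or s.n_atoms() == 0:
        raise EmptyStructureError("cannot write an empty structure")
    lines = []
    serial = 0
    for cid, residues in s.chains.items():
        for res in residues:
            num, icode = _split_seq_id(res.seq_id)
            for a in res.atoms:
                serial += 1
                if len(a.name) > 4:
                    raise PDBError(f"atom name {a.name!r} exceeds 4 characters")
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.coords
                lines.append(
                    f"ATOM  {serial:5d} {name}{a.altloc or ' ':1s}{res.name:>3s} "
                    f"{cid[:1]:1s}{num:4d}{icode:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}")
        serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1].name:>3s} "
                     f"{cid[:1]:1s}{_split_seq_id(residues[-1].seq_id)[0]:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _split_seq_id(seq_id: str) -> tuple[int, str]:
    digits = seq_id
    icode = " "
    if seq_id and seq_id[-1].isalpha():
        digits, icode = seq_id[:-1], seq_id[-1]
    return int(digits), icode


def assign_radii(s: Structure, radius_set: str = DEFAULT_RADIUS_TABLE) -> Structure:
    """Return a copy of *s* with van-der-Waals radii set from a named table."""
    try:
        table = RADIUS_TABLES[radius_set]
    except KeyError:
        raise KeyError(
            f"unknown radius set {radius_set!r}; available: {sorted(RADIUS_TABLES)}"
        ) from None
    out = s.copy()
    for cid, residues in out.chains.items():
        for res in residues:
            for a in res.atoms:
                r = table.get(a.element)
                if r is None:
                    raise KeyError(
                        f"no radius for element {a.element!r} "
                        f"(atom {a.name} in {res.name} {res.seq_id}, chain {cid})")
                a.radius = r
    return out
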