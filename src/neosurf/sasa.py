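"""Solvent-accessible surface area by Shrake-Rupley quadrature.

For every atom a set of quadrature points is distributed on the expanded
sphere of radius ``r + probe``; the accessible fraction is the share of
points not inside any neighboring expanded sphere, and

    area_i = accessible_fraction_i * 4 * pi * (r_i + probe)^2 .

The point set is a deterministic generalized (golden) spiral, so the whole
computation is reproducible with no random state.  Per-residue areas are
decomposed into backbone/side-chain and apolar (C + S) contributions, and
residues are annotated buried ("in") or solvent exposed ("out") from the
ratio of the side-chain area to a fully exposed reference: the same side
chain in an ideal-geometry extended Gly-X-Gly tripeptide.  By default a
residue is "out" above 50% relative exposure and "in" below 20%, the
convention popularized by the GETAREA server.

Glycine has no side-chain heavy atoms; its ratio is defined as 0 and its
flag is computed from the backbone area against a Gly-Gly-Gly backbone
reference instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .chem import APOLAR_ELEMENTS, DEFAULT_RADIUS_TABLE, STANDARD_AA1, ONE_TO_THREE
from .structure import Atom, Structure, assign_radii

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
RATIO_HI = 50.0
RATIO_LO = 20.0


@lru_cache(maxsize=64)
def spiral_points(n: int) -> np.ndarray:
    """*n* deterministic, near-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    pts = np.empty((n, 3))
    pts[:, 0] = np.sin(phi) * np.cos(theta)
    pts[:, 1] = np.sin(phi) * np.sin(theta)
    pts[:, 2] = np.cos(phi)
    return pts


def _check_atoms(atoms: list[Atom]) -> tuple[np.ndarray, np.ndarray]:
    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array([a.radius for a in atoms], dtype=float)
    if coords.size and not np.all(np.isfinite(coords)):
        raise ValueError("non-finite atom coordinate")
    if np.any(radii <= 0):
        bad = [atoms[i].name for i in np.where(radii <= 0)[0][:5]]
        raise ValueError(f"atoms without an assigned radius: {bad}")
    return coords, radii


def atom_sasa(atoms: list[Atom], probe: float = DEFAULT_PROBE,
              n_points: int = DEFAULT_N_POINTS,
              subset: np.ndarray | list[int] | None = None) -> np.ndarray:
    """Per-atom SASA (A^2) of *atoms* in their mutual occlusion context.

    *subset* restricts which atoms' areas are computed (all atoms still
    occlude); the returned array is aligned with the subset order.
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 32:
        raise ValueError("n_points must be at least 32")
    coords, radii = _check_atoms(atoms)
    n = len(atoms)
    idx = np.arange(n) if subset is None else np.asarray(subset, dtype=int)
    if n == 0 or idx.size == 0:
        return np.zeros(0)
    expanded = radii + probe
    unit = spiral_points(n_points)
    tree = cKDTree(coords)
    max_cut = 2.0 * radii.max() + 2.0 * probe
    areas = np.empty(idx.size)
    for out_i, i in enumerate(idx):
        cand = tree.query_ball_point(coords[i], max_cut + 1e-9)
        cand = [j for j in cand if j != i]
        if cand:
            d = np.linalg.norm(coords[cand] - coords[i], axis=1)
            cut = radii[i] + radii[cand] + 2.0 * probe
            nb = [j for j, dj, cj in zip(cand, d, cut) if dj < cj]
        else:
            nb = []
        sphere = coords[i] + expanded[i] * unit
        if nb:
            nb = np.asarray(nb)
            # blocked if strictly inside a neighbor's expanded sphere
            d2 = ((sphere[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            blocked = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            free = int(n_points - blocked.sum())
        else:
            free = n_points
        areas[out_i] = free / n_points * 4.0 * math.pi * expanded[i] ** 2
    return areas


@dataclass
class ResidueRow:
    chain: str
    seq_id: str
    residue: str            # 3-letter code
    one_letter: str
    total: float
    apolar: float
    backbone: float
    sidechain: float
    ratio: float | None = None      # percent relative side-chain exposure
    flag: str = "unassigned"        # in / out / unassigned


@dataclass
class SASAReport:
    """Per-residue surface-area decomposition for one peptide chain."""

    rows: list[ResidueRow]
    structure_total: float
    probe_radius: float
    n_points: int
    radius_set: str = DEFAULT_RADIUS_TABLE

    def row_for(self, position: int) -> ResidueRow:
        """Row at 1-based *position* along the reported chain."""
        return self.rows[position - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def write_tsv(self, path_or_buffer) -> None:
        df = self.to_frame()[["chain", "seq_id", "residue", "total", "apolar",
                              "backbone", "sidechain", "ratio", "flag"]]
        df.to_csv(path_or_buffer, sep="\t", index=False, float_format="%.3f")


def residue_sasa(s: Structure, chain: str, probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS,
                 radius_set: str = DEFAULT_RADIUS_TABLE) -> SASAReport:
    """Per-residue SASA of *chain*, occluded by the full structure.

    All chains of *s* contribute to occlusion; only the residues of *chain*
    are reported.  *radius_set* must name the table the structure's radii
    were assigned from — it is used to build matching reference tripeptides
    during annotation.
    """
    if chain not in s.chains:
        raise KeyError(f"chain {chain!r} not in structure (has {sorted(s.chains)})")
    all_atoms = list(s.atoms())
    owner: list[tuple[int, int]] = []   # (residue index in chain, atom index)
    pos = 0
    for cid, residues in s.chains.items():
        for ri, res in enumerate(residues):
            for _ in res.atoms:
                if cid == chain:
                    owner.append((ri, pos))
                pos += 1
    subset = np.array([p for _, p in owner], dtype=int)
    areas = atom_sasa(all_atoms, probe, n_points, subset=subset)

    residues = s.chains[chain]
    rows = []
    cursor = 0
    for ri, res in enumerate(residues):
        n_at = len(res.atoms)
        res_areas = areas[cursor:cursor + n_at]
        cursor += n_at
        bb = sum(a for a, atom in zip(res_areas, res.atoms) if atom.is_backbone)
        sc = sum(a for a, atom in zip(res_areas, res.atoms) if not atom.is_backbone)
        ap = sum(a for a, atom in zip(res_areas, res.atoms)
                 if atom.element in APOLAR_ELEMENTS)
        rows.append(ResidueRow(chain=chain, seq_id=res.seq_id, residue=res.name,
                               one_letter=res.one_letter, total=bb + sc,
                               apolar=ap, backbone=bb, sidechain=sc))
    return SASAReport(rows=rows, structure_total=float(sum(r.total for r in rows)),
                      probe_radius=probe, n_points=n_points, radius_set=radius_set)


@lru_cache(maxsize=None)
def reference_sidechain_area(residue_type: str, probe: float = DEFAULT_PROBE,
                             n_points: int = DEFAULT_N_POINTS,
                             radius_set: str = DEFAULT_RADIUS_TABLE) -> float:
    """Side-chain SASA of residue X in an ideal extended Gly-X-Gly tripeptide.

    This is the fully exposed reference that relative side-chain exposure is
    measured against.  Glycine's value is 0 by construction.
    """
    residue_type = residue_type.upper()
    if residue_type not in STANDARD_AA1:
        raise KeyError(f"not a standard amino acid: {residue_type!r}")
    if residue_type == "G":
        return 0.0
    return _reference_areas(residue_type, probe, n_points, radius_set)[0]


@lru_cache(maxsize=None)
def reference_backbone_area(residue_type: str, probe: float = DEFAULT_PROBE,
                            n_points: int = DEFAULT_N_POINTS,
                            radius_set: str = DEFAULT_RADIUS_TABLE) -> float:
    """Backbone SASA of the central residue of an extended Gly-X-Gly tripeptide."""
    residue_type = residue_type.upper()
    if residue_type not in STANDARD_AA1:
        raise KeyError(f"not a standard amino acid: {residue_type!r}")
    return _reference_areas(residue_type, probe, n_points, radius_set)[1]


def _reference_areas(x: str, probe: float, n_points: int,
                     radius_set: str) -> tuple[float, float]:
    from .peptides import build_extended_peptide

    tri = build_extended_peptide(f"G{x}G")
    tri = assign_radii(tri, radius_set)
    report = residue_sasa(tri, "A", probe, n_points, radius_set)
    row = report.rows[1]
    return row.sidechain, row.backbone


def annotate_in_out(report: SASAReport, ratio_hi: float = RATIO_HI,
                    ratio_lo: float = RATIO_LO) -> SASAReport:
    """Annotate each residue buried ("in") or exposed ("out").

    ``exposure_ratio = sidechain_area / reference_sidechain_area * 100``;
    a residue is "out" above *ratio_hi* percent, "in" below *ratio_lo*, and
    "unassigned" in between.  Glycine is flagged from its backbone area
    against the Gly-Gly-Gly backbone reference, with ratio reported as 0.
    """
    if not ratio_lo < ratio_hi:
        raise ValueError("require ratio_lo < ratio_hi")
    new_rows = []
    for row in report.rows:
        row = replace(row)
        if row.one_letter not in STANDARD_AA1:
            row.ratio, row.flag = None, "unassigned"
        elif row.one_letter == "G":
            ref_bb = reference_backbone_area("G", report.probe_radius,
                                             report.n_points, report.radius_set)
            bb_ratio = 100.0 * row.backbone / ref_bb if ref_bb > 0 else 0.0
            row.ratio = 0.0
            row.flag = ("out" if bb_ratio > ratio_hi
                        else "in" if bb_ratio < ratio_lo else "unassigned")
        else:
            ref = reference_sidechain_area(row.one_letter, report.probe_radius,
                                           report.n_points, report.radius_set)
            row.ratio = 100.0 * row.sidechain / ref if ref > 0 else 0.0
            row.flag = ("out" if row.ratio > ratio_hi
                        else "in" if row.ratio < ratio_lo else "unassigned")
        new_rows.append(row)
    return replace(report, rows=new_rows)
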