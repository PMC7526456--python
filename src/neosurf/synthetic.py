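"""Synthetic structures with known ground truth.

Real peptide-MHC crystal structures cannot be bundled with the package, so
every stage is exercised against a parameterized *toy groove*: a slab of
packed pseudo-atoms (the beta-sheet floor) flanked by two atom rows (the
alpha-helix walls), with an extended peptide laid along the groove axis.
Each side chain is built pointing either toward solvent (+z, "up") or into
the floor (-z, "down"); down-pointing side chains sink into a snugly
carved cavity in the slab, so the generator knows the expected
buried/exposed flag of every position at generation time.

The groove is an occlusion-geometry abstraction, not a folded MHC: it
reproduces the *solvation environment* of a presented peptide (open top,
packed floor, flanking walls), nothing else.

Also provided: seeded random atom clouds for surface-area oracles, and
synthetic template sets with prescribed sequence similarity and
mutant-position exposure, mirroring the candidate pools a template search
over real H-2Kb / H-2Db entries would return.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .chem import DEFAULT_RADIUS_TABLE, ONE_TO_THREE, RADIUS_TABLES
from .epitopes import MEP
from .peptides import ideal_residue, place_side_chain
from .structure import Atom, Residue, Structure, write_pdb
from .templates import TemplateEntry


class GrooveError(ValueError):
    """Invalid groove geometry request."""


@dataclass(frozen=True)
class GrooveSpec:
    """Geometry of the toy groove (all lengths in Angstrom).

    Defaults are sized for 8-10-mer peptides: a floor deep enough to bury
    an extended arginine side chain, and walls far enough apart that an
    up-pointing side chain is never occluded by them (checked at
    generation time).
    """

    floor_top: float = -2.0          # z of the uppermost floor layer
    floor_depth: float = 9.6         # slab thickness below floor_top
    floor_spacing: float = 1.5       # pseudo-atom grid spacing
    floor_margin: float = 4.0        # slab overhang beyond the peptide ends
    wall_separation: float = 20.0    # distance between the two wall rows
    wall_radius: float = 1.7
    wall_height: float = 4.0
    peptide_rise: float = 6.5        # per-residue translation along the axis
    updown_shift: float = 1.8        # vertical residue offset (+ for up, - for down)
    tilt_deg: float = 22.0           # alternating side-chain splay along the axis
    clearance: float = 0.4           # carved gap between side chain and floor
    jitter: float = 0.05             # seeded positional noise on pseudo-atoms
    capacity: int = 10               # longest peptide the groove accepts
    probe: float = 1.4               # probe used for the wall-clearance check
    radius_set: str = DEFAULT_RADIUS_TABLE
    seed: int = 0


def _align_rotation(v: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Smallest rotation taking direction *v* onto direction *target*."""
    v = v / np.linalg.norm(v)
    t = target / np.linalg.norm(target)
    axis = np.cross(v, t)
    s = np.linalg.norm(axis)
    c = float(v @ t)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # v antiparallel to target: rotate pi about any perpendicular axis
        perp = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(v, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / s
    K = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _ala_local_frame() -> dict[str, np.ndarray]:
    """Backbone atom positions of an ideal residue, in a CA-centered frame
    with the side chain along +z and the N->C direction along +x."""
    res = ideal_residue("ALA")
    ca = res.atom("CA").coords
    z = res.atom("CB").coords - ca
    z = z / np.linalg.norm(z)
    x = res.atom("C").coords - res.atom("N").coords
    x = x - (x @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    basis = np.stack([x, y, z])
    return {name: basis @ (res.atom(name).coords - ca)
            for name in ("N", "CA", "C", "O")}


def make_groove_complex(sequence: str, pattern: str | list[str],
                        spec: GrooveSpec = GrooveSpec(),
                        structure_id: str = "groove") -> tuple[Structure, list[str]]:
    """Build a toy groove complex and return it with its expected flags.

    *pattern* gives one of ``up``/``down`` (or ``u``/``d``) per residue;
    the returned labels are the expected annotation flags: ``out`` for up
    positions, ``in`` for down positions.  Deterministic given
    ``spec.seed``.
    """
    sequence = sequence.upper()
    pat = [p[0].lower() for p in
           (pattern if isinstance(pattern, (list, tuple)) else list(pattern))]
    if len(pat) != len(sequence):
        raise GrooveError("pattern length must match sequence length")
    if any(p not in "ud" for p in pat):
        raise GrooveError("pattern entries must be 'up' or 'down'")
    if len(sequence) > spec.capacity:
        raise GrooveError(
            f"sequence of {len(sequence)} residues exceeds groove capacity "
            f"{spec.capacity}")
    table = RADIUS_TABLES[spec.radius_set]
    local = _ala_local_frame()
    rng = np.random.default_rng(spec.seed)

    residues = []
    for i, one in enumerate(sequence):
        flip = 1.0 if pat[i] == "u" else -1.0
        # up residues ride high, down residues sink toward the floor — the
        # zigzag of a presented peptide's backbone, exaggerated
        shift = np.array([spec.peptide_rise * i, 0.0, flip * spec.updown_shift])
        # alternate splay about the groove axis so neighboring side chains
        # do not shadow each other (presented peptides fan their side chains)
        tilt = np.radians(spec.tilt_deg) * (1.0 if i % 2 else -1.0)
        ct, st = np.cos(tilt), np.sin(tilt)
        Ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
        world = {name: Ry @ np.array([v[0], flip * v[1], flip * v[2]]) + shift
                 for name, v in local.items()}
        atoms = [Atom("N", "N", world["N"], radius=table["N"], is_backbone=True),
                 Atom("CA", "C", world["CA"], radius=table["C"], is_backbone=True),
                 Atom("C", "C", world["C"], radius=table["C"], is_backbone=True),
                 Atom("O", "O", world["O"], radius=table["O"], is_backbone=True)]
        side = place_side_chain({k: world[k] for k in ("N", "CA", "C")}, one)
        if side:
            # point the side-chain *centroid* (not just the CA-CB bond)
            # along the tilted vertical, rotating the whole residue about CA
            target = Ry @ np.array([0.0, 0.0, flip])
            centroid = np.mean([a.coords for a in side], axis=0)
            R = _align_rotation(centroid - world["CA"], target)
            ca = world["CA"]
            for a in atoms + side:
                a.coords = R @ (a.coords - ca) + ca
        for sc in side:
            sc.radius = table[sc.element]
            atoms.append(sc)
        residues.append(Residue(ONE_TO_THREE[one], str(i + 1), atoms))

    pep_coords = np.array([a.coords for r in residues for a in r.atoms])
    pep_radii = np.array([a.radius for r in residues for a in r.atoms])
    tree = cKDTree(pep_coords)

    # floor slab with carved cavities around everything that dips into it
    length = spec.peptide_rise * (len(sequence) - 1)
    xs = np.arange(-spec.floor_margin, length + spec.floor_margin + 1e-9,
                   spec.floor_spacing)
    half_w = spec.wall_separation / 2.0
    ys = np.arange(-half_w, half_w + 1e-9, spec.floor_spacing)
    zs = np.arange(spec.floor_top - spec.floor_depth, spec.floor_top + 1e-9,
                   spec.floor_spacing)
    grid = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
    grid = grid + rng.normal(0.0, spec.jitter, grid.shape)
    r_floor = table["C"]
    keep = np.ones(len(grid), dtype=bool)
    max_cut = r_floor + pep_radii.max() + spec.clearance
    for gi, neighbors in enumerate(tree.query_ball_point(grid, max_cut)):
        for pj in neighbors:
            d = np.linalg.norm(grid[gi] - pep_coords[pj])
            if d < r_floor + pep_radii[pj] + spec.clearance:
                keep[gi] = False
                break
    floor_atoms = [Atom("DU", "C", c, radius=r_floor) for c in grid[keep]]

    wall_atoms = []
    wx = np.arange(-spec.floor_margin, length + spec.floor_margin + 1e-9, 2.4)
    wz = np.arange(spec.floor_top + 1.2, spec.floor_top + 1.2 + spec.wall_height + 1e-9, 2.4)
    for side in (-half_w, half_w):
        for x in wx:
            for z in wz:
                c = np.array([x, side, z]) + rng.normal(0.0, spec.jitter, 3)
                wall_atoms.append(Atom("DU", "C", c, radius=spec.wall_radius))

    # wall-separation invariant: up side chains must be unoccluded by walls
    wall_coords = np.array([a.coords for a in wall_atoms])
    for i, res in enumerate(residues):
        if pat[i] != "u":
            continue
        for a in res.atoms:
            if a.is_backbone:
                continue
            d = np.linalg.norm(wall_coords - a.coords, axis=1).min()
            if d <= a.radius + spec.wall_radius + 2.0 * spec.probe:
                raise GrooveError(
                    f"wall_separation {spec.wall_separation} too narrow: wall "
                    f"occludes up side chain at position {i + 1}")

    groove = [Residue("DUM", "1", floor_atoms), Residue("DUM", "2", wall_atoms)]
    chains = {"P": residues, "M": groove}
    pep_chain = "P" if 8 <= len(sequence) <= 10 else None
    s = Structure(chains, id=structure_id, peptide_chain=pep_chain, mhc_chain="M")
    labels = ["out" if p == "u" else "in" for p in pat]
    return s, labels


def random_atom_cloud(n: int, box: float = 10.0, min_sep: float = 1.5,
                      seed: int = 0,
                      radius_set: str = DEFAULT_RADIUS_TABLE) -> list[Atom]:
    """Seeded random atoms in a cubic box, pairwise at least *min_sep* apart.

    Elements are drawn from C/N/O/S with radii from *radius_set* — a
    structureless substrate for surface-area oracle comparisons.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    table = RADIUS_TABLES[radius_set]
    elements = rng.choice(["C", "N", "O", "S"], size=n)
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError(
                f"could not pack {n} atoms at min_sep={min_sep} in box={box}")
        p = rng.uniform(0.0, box, 3)
        if all(np.linalg.norm(p - q) >= min_sep for q in coords):
            coords.append(p)
    return [Atom(f"X{i+1}", el, c, radius=table[el])
            for i, (el, c) in enumerate(zip(elements, coords))]


# substitution targets guaranteed dissimilar (BLOSUM62 <= 0) for any original
_DISSIMILAR = {
    "A": "DNEKRW", "R": "ALVIFWD", "N": "LIVFWAC", "D": "LIVFWYC",
    "C": "DEKRNQ", "Q": "ILVFWAC", "E": "ILVFWC",  "G": "ILVFYKR",
    "H": "ILVAC",  "I": "DEKRNQG", "L": "DENQKG",  "K": "ILVFWC",
    "M": "DNGPK",  "F": "DEKRNQG", "P": "ILVFWYD", "S": "ILVFWY",
    "T": "DEWFG",  "W": "DEKRNQ",  "Y": "DEKRAG",  "V": "DEKRNQG",
}


def make_template_set(n_templates: int, mep: MEP,
                      similarity_spread=None,
                      seed: int = 0,
                      exposures: list[str] | None = None,
                      spec: GrooveSpec = GrooveSpec(),
                      out_dir: str | None = None,
                      ) -> tuple[list[TemplateEntry], pd.DataFrame]:
    """Synthetic candidate templates for *mep* with known properties.

    Each template is a toy-groove complex whose peptide sequence has a
    prescribed percent identity to the MEP (replaced positions get
    substitution-matrix-dissimilar residues, so the identity and
    similarity-mode scores coincide) and whose residue at the position
    aligned to the MEP's mutant position points ``up`` (exposure "out") or
    ``down`` ("in") as prescribed.  Non-mutant positions follow the
    canonical anchor pattern: position 2 and the C-terminal residue point
    down, all others up.

    Returns the template entries plus a ground-truth table.  When
    *out_dir* is given, PDB files and a ``manifest.tsv`` are written there.
    """
    if n_templates < 1:
        raise ValueError("need n_templates >= 1")
    L = len(mep.sequence)
    if similarity_spread is None:
        similarity_spread = np.linspace(100.0, 40.0, n_templates).tolist()
    if len(similarity_spread) != n_templates:
        raise ValueError("similarity_spread length must equal n_templates")
    exposures = exposures or ["out"] * n_templates
    if len(exposures) != n_templates:
        raise ValueError("exposures length must equal n_templates")

    rng = np.random.default_rng(seed)
    entries, truth = [], []
    for t in range(n_templates):
        target = float(similarity_spread[t])
        if not 0.0 <= target <= 100.0:
            raise ValueError(f"similarity target {target} outside [0, 100]")
        k = int(round(target / 100.0 * L))
        achieved = 100.0 * k / L
        if abs(achieved - target) > 100.0 / (2.0 * L):
            raise ValueError(
                f"similarity {target}% unreachable for a {L}-mer "
                f"(closest achievable: {achieved:.1f}%)")
        want = exposures[t]
        if want not in ("out", "in"):
            raise ValueError("exposures entries must be 'out' or 'in'")
        mut_idx = mep.mutant_pos - 1
        if want == "in" and k >= 1:
            # buried pockets are residue-matched at the mutant position: a
            # rigid scaffold cannot repack an oversized cavity, so a buried
            # ground truth is only guaranteed for a size-matched side chain
            others = [i for i in range(L) if i != mut_idx]
            kept = {mut_idx} | set(
                rng.choice(others, size=k - 1, replace=False).tolist())
        else:
            kept = set(rng.choice(L, size=k, replace=False).tolist())
        seq = []
        for i, orig in enumerate(mep.sequence):
            if i in kept:
                seq.append(orig)
            else:
                options = [c for c in _DISSIMILAR[orig] if c not in "GP"]
                seq.append(options[rng.integers(len(options))])
        seq = "".join(seq)

        pattern = ["u"] * L
        pattern[1] = "d"          # canonical anchor positions
        pattern[L - 1] = "d"
        pattern[mut_idx] = "u" if want == "out" else "d"

        template_id = f"SYN-{t + 1:03d}"
        child_seed = int(rng.integers(2**31 - 1))
        struct, labels = make_groove_complex(
            seq, pattern, replace(spec, seed=child_seed), structure_id=template_id)
        entry = TemplateEntry(template_id=template_id, allele=mep.allele,
                              peptide_chain="P", structure=struct)
        entries.append(entry)
        truth.append({"template_id": template_id, "peptide_seq": seq,
                      "target_similarity": target, "achieved_identity": achieved,
                      "mutant_exposure": want,
                      "labels": "".join(x[0] for x in labels)})
    truth_df = pd.DataFrame(truth)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        rows = []
        for e in entries:
            path = os.path.join(out_dir, f"{e.template_id}.pdb")
            with open(path, "w") as fh:
                fh.write(write_pdb(e.structure))
            rows.append({"template_id": e.template_id, "path": f"{e.template_id}.pdb",
                         "allele": e.allele, "peptide_chain": e.peptide_chain})
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.tsv"),
                                  sep="\t", index=False)
        truth_df.to_csv(os.path.join(out_dir, "ground_truth.tsv"),
                        sep="\t", index=False)
    return entries, truth_df
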