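"""Approximate MEP-MHC model building.

The full homology-modeling + peptide-docking stack that a production
structural study would use is replaced by a transparent, deterministic
three-step procedure:

1. **graft** — the MEP sequence is threaded onto the selected template's
   peptide backbone: backbone atoms are copied verbatim, identical residue
   types keep the template side chain, differing types are rebuilt with
   ideal geometry (chi angles copied from the template where the torsion
   tree is shared, otherwise the embedded most-common rotamer);
2. **clash scoring** — a soft-sphere overlap penalty,
   ``sum over non-bonded pairs of max(0, r_i + r_j - d_ij)^2``, with 1-2
   and 1-3 bonded pairs excluded;
3. **refine** — seeded multi-restart side-chain torsion search: each
   restart perturbs the peptide's chi angles and greedily minimizes the
   clash score on a torsion grid; half the restarts first run a coarse
   30-degree grid pass.  The backbone never moves.

The clash score is a steric proxy, not a physical energy; model selection
keeps the published logic (desired mutant-residue exposure first, lowest
score second) while making every step reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._geom import place_atom
from .chem import (
    CHI_ATOMS,
    DEFAULT_RADIUS_TABLE,
    ONE_TO_THREE,
    RADIUS_TABLES,
    STANDARD_AA3,
    chi_moved_atoms,
    residue_template,
)
from .epitopes import MEP
from .peptides import get_chi, ideal_residue, place_side_chain, set_chi, _BB
from .sasa import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
    RATIO_HI,
    RATIO_LO,
    annotate_in_out,
    residue_sasa,
)
from .structure import Atom, Residue, Structure
from .superpose import ca_rmsd


@dataclass
class BuiltModel:
    structure: Structure
    clash_score: float
    seed: int
    n_restarts: int
    template_id: str = ""
    ca_rmsd_to_template: float = 0.0
    mutant_flag: str | None = None
    warning: str | None = None


class GraftError(ValueError):
    pass


def graft_peptide(template: Structure, mep: MEP, *,
                  trim: str = "cterm",
                  radius_set: str = DEFAULT_RADIUS_TABLE) -> Structure:
    """Thread the MEP sequence onto the template's peptide backbone.

    Lengths may differ by at most one residue: a longer template peptide is
    trimmed at the *trim* terminus, a shorter one is extended at the
    C-terminus with an ideal extended residue.  Residues whose type matches
    the template keep the template's atoms bit-identically; the MHC chains
    are copied unchanged.
    """
    if template.peptide_chain is None:
        raise GraftError("template has no peptide_chain set")
    if trim not in ("cterm", "nterm"):
        raise GraftError("trim must be 'cterm' or 'nterm'")
    table = RADIUS_TABLES[radius_set]
    tpl_res = [r.copy() for r in template.chains[template.peptide_chain]]
    L, Lt = len(mep.sequence), len(tpl_res)
    if abs(L - Lt) > 1:
        raise GraftError(
            f"template peptide length {Lt} differs from MEP length {L} by more "
            "than 1")
    if Lt == L + 1:
        tpl_res = tpl_res[:-1] if trim == "cterm" else tpl_res[1:]
    elif Lt == L - 1:
        tpl_res = tpl_res + [_extend_cterm(tpl_res)]

    new_residues = []
    for i, one in enumerate(mep.sequence):
        resname = ONE_TO_THREE[one]
        src = tpl_res[i]
        if src.name == resname:
            res = src.copy()
            res.seq_id = str(i + 1)
        else:
            backbone = [a.copy() for a in src.atoms if a.is_backbone]
            missing = {"N", "CA", "C"} - {a.name for a in backbone}
            if missing:
                raise GraftError(
                    f"template residue {src.name} {src.seq_id} lacks backbone "
                    f"atoms {sorted(missing)}")
            frame = {a.name: a.coords for a in backbone}
            chi_source = src if src.name in STANDARD_AA3 else None
            side = place_side_chain(frame, one, chi_source=chi_source)
            for a in side:
                a.radius = table[a.element]
            res = Residue(resname, str(i + 1), backbone + side)
        new_residues.append(res)

    chains = {}
    for cid, residues in template.chains.items():
        if cid == template.peptide_chain:
            chains[cid] = new_residues
        else:
            chains[cid] = [r.copy() for r in residues]
    return Structure(chains, id=f"{mep.name}_on_{template.id or 'template'}",
                     peptide_chain=template.peptide_chain,
                     mhc_chain=template.mhc_chain)


def _extend_cterm(residues: list[Residue]) -> Residue:
    """One extra glycine-like backbone frame continuing the chain, extended."""
    last = residues[-1]
    for name in ("N", "CA", "C"):
        if not last.has_atom(name):
            raise GraftError("cannot extend: terminal backbone incomplete")
    n0, ca0, c0 = (last.atom(x).coords for x in ("N", "CA", "C"))
    n = place_atom(n0, ca0, c0, _BB["C_N"], _BB["CA_C_N"], 135.0)
    ca = place_atom(ca0, c0, n, _BB["N_CA"], _BB["C_N_CA"], 180.0)
    c = place_atom(c0, n, ca, _BB["CA_C"], _BB["N_CA_C"], -139.0)
    o = place_atom(n, ca, c, _BB["C_O"], _BB["CA_C_O"], 135.0 + 180.0)
    table = RADIUS_TABLES[DEFAULT_RADIUS_TABLE]
    atoms = [Atom("N", "N", n, radius=table["N"], is_backbone=True),
             Atom("CA", "C", ca, radius=table["C"], is_backbone=True),
             Atom("C", "C", c, radius=table["C"], is_backbone=True),
             Atom("O", "O", o, radius=table["O"], is_backbone=True)]
    return Residue("GLY", str(len(residues) + 1), atoms)


# ---------------------------------------------------------------------------
# clash scoring

def _flat_atoms(s: Structure):
    """Flatten to (atoms, coords, radii, exclusion sets, rigid-group ids).

    Exclusions cover bonded pairs up to graph distance 3 (1-2, 1-3 and the
    torsion-defining 1-4 pairs), so ideal-geometry rotamers score zero and
    refinement cannot "improve" a model by distorting intrinsic contacts.
    All non-amino-acid residues of one chain (pseudo-atom scaffolds) share
    a rigid group and are never scored against each other.
    """
    atoms: list[Atom] = []
    index: dict[tuple[str, int, str], int] = {}
    group: list[int] = []
    res_list: list[tuple[str, int, Residue]] = []
    chain_gid = {cid: k + 1 for k, cid in enumerate(s.chains)}
    for cid, residues in s.chains.items():
        for ri, res in enumerate(residues):
            res_list.append((cid, ri, res))
            rigid = res.name not in STANDARD_AA3
            for a in res.atoms:
                index[(cid, ri, a.name)] = len(atoms)
                atoms.append(a)
                group.append(chain_gid[cid] if rigid else -1)
    bonds: list[tuple[int, int]] = []
    for cid, ri, res in res_list:
        if res.name in STANDARD_AA3:
            _, _, _, tpl_bonds = residue_template(res.name)
            for pair in tpl_bonds:
                a, b = tuple(pair)
                ia = index.get((cid, ri, a))
                ib = index.get((cid, ri, b))
                if ia is not None and ib is not None:
                    bonds.append((ia, ib))
        nxt = index.get((cid, ri + 1, "N"))
        cur = index.get((cid, ri, "C"))
        if nxt is not None and cur is not None:
            bonds.append((cur, nxt))
    adj: list[set[int]] = [set() for _ in atoms]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    excl: list[set[int]] = [set() for _ in atoms]
    for i in range(len(atoms)):
        frontier = {i}
        seen = {i}
        for _ in range(3):          # graph distance 1..3
            frontier = {k for f in frontier for k in adj[f]} - seen
            seen |= frontier
            excl[i] |= frontier
    coords = np.array([a.coords for a in atoms]) if atoms else np.empty((0, 3))
    radii = np.array([a.radius for a in atoms])
    return atoms, coords, radii, excl, np.array(group, dtype=int)


def clash_score(s: Structure) -> float:
    """Soft-sphere overlap penalty over non-bonded atom pairs.

    ``sum over pairs of max(0, r_i + r_j - d_ij)^2`` with bonded pairs up
    to graph distance 3 excluded and rigid pseudo-atom scaffolds not scored
    against themselves.
    """
    atoms, coords, radii, excl, group = _flat_atoms(s)
    if len(atoms) and np.any(radii <= 0):
        raise ValueError("clash_score requires assigned radii")
    if len(atoms) < 2:
        return 0.0
    tree = cKDTree(coords)
    cutoff = 2.0 * radii.max()
    total = 0.0
    for i, j in tree.query_pairs(cutoff):
        if j in excl[i]:
            continue
        if group[i] != -1 and group[i] == group[j]:
            continue
        d = np.linalg.norm(coords[i] - coords[j])
        overlap = radii[i] + radii[j] - d
        if overlap > 0:
            total += overlap * overlap
    return float(total)


class _TorsionSampler:
    """Greedy chi-grid clash minimization over the peptide side chains."""

    def __init__(self, model: Structure):
        self.structure = model.copy()
        self.pc = model.peptide_chain
        if self.pc is None:
            raise ValueError("refine requires peptide_chain set")
        atoms, coords, radii, excl, _ = _flat_atoms(self.structure)
        self.atoms, self.coords, self.radii, self.excl = atoms, coords, radii, excl
        flat_i = 0
        res_index: dict[tuple[str, int, str], int] = {}
        for cid, residues in self.structure.chains.items():
            for ri, res in enumerate(residues):
                for a in res.atoms:
                    res_index[(cid, ri, a.name)] = flat_i
                    flat_i += 1
        self.rotatable: list[tuple[Residue, int, np.ndarray, tuple[int, int]]] = []
        flexible: set[int] = set()
        for ri, res in enumerate(self.structure.chains[self.pc]):
            if res.name not in CHI_ATOMS:
                continue
            for ci, quad in enumerate(CHI_ATOMS[res.name]):
                if not all(res.has_atom(n) for n in quad):
                    break
                moved_names = chi_moved_atoms(res.name)[ci]
                moved = np.array([res_index[(self.pc, ri, n)] for n in moved_names
                                  if (self.pc, ri, n) in res_index], dtype=int)
                if moved.size == 0:
                    continue
                axis = (res_index[(self.pc, ri, quad[1])],
                        res_index[(self.pc, ri, quad[2])])
                self.rotatable.append((res, ci, moved, axis))
                flexible.update(moved.tolist())
        self.flexible = np.array(sorted(flexible), dtype=int)
        static_mask = np.ones(len(self.atoms), dtype=bool)
        static_mask[self.flexible] = False
        self.static_idx = np.where(static_mask)[0]
        self.static_tree = (cKDTree(self.coords[self.static_idx])
                            if self.static_idx.size else None)
        self.max_r = float(self.radii.max()) if len(self.atoms) else 0.0

    def partial_score(self, moved: np.ndarray) -> float:
        """Clash energy of *moved* atoms against everything else."""
        total = 0.0
        moved_set = set(moved.tolist())
        for i in moved:
            ci = self.coords[i]
            cutoff = self.radii[i] + self.max_r
            if self.static_tree is not None:
                for jj in self.static_tree.query_ball_point(ci, cutoff):
                    j = int(self.static_idx[jj])
                    if j in self.excl[i]:
                        continue
                    overlap = self.radii[i] + self.radii[j] - np.linalg.norm(ci - self.coords[j])
                    if overlap > 0:
                        total += overlap * overlap
            for j in self.flexible:
                j = int(j)
                if j in moved_set or j in self.excl[i]:
                    continue
                overlap = self.radii[i] + self.radii[j] - np.linalg.norm(ci - self.coords[j])
                if overlap > 0:
                    total += overlap * overlap
        return total

    def try_chi(self, rot_idx: int, value: float) -> float:
        """Set chi, refresh cache, return the move's partial score."""
        res, ci, moved, _ = self.rotatable[rot_idx]
        set_chi(res, ci, value)
        for gi in moved:
            self.coords[gi] = self.atoms[gi].coords
        return self.partial_score(moved)

    def chi_value(self, rot_idx: int) -> float:
        res, ci, _, _ = self.rotatable[rot_idx]
        return get_chi(res)[ci]

    def total_score(self) -> float:
        return clash_score(self.structure)


def refine(model: Structure, n_restarts: int = 200, seed: int = 0, *,
           sigma_deg: float = 20.0, max_sweeps: int = 4,
           template: Structure | None = None,
           template_id: str = "",
           return_candidates: bool = False):
    """Seeded multi-restart side-chain clash minimization.

    Each restart perturbs every peptide chi angle by a Gaussian kick and
    greedily walks a torsion grid downhill in clash score; the first half
    of the restarts prepends a coarse 30-degree whole-circle pass.  Only
    side-chain torsions move — the backbone is rigid, so the C-alpha trace
    (and hence the C-alpha RMSD to the template) is untouched.

    Returns the best :class:`BuiltModel`, or all restart candidates when
    *return_candidates* (sorted by clash score ascending).  Output is a
    deterministic function of (model, seed, n_restarts).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    base = _TorsionSampler(model)
    initial_score = base.total_score()
    rmsd0 = (ca_rmsd(model, template) if template is not None else 0.0)

    def as_model(structure: Structure, score: float) -> BuiltModel:
        return BuiltModel(structure=structure, clash_score=score, seed=seed,
                          n_restarts=n_restarts, template_id=template_id,
                          ca_rmsd_to_template=rmsd0)

    if initial_score == 0.0 or not base.rotatable:
        result = as_model(model.copy(), initial_score)
        return [result] if return_candidates else result

    fine_deltas = (-30.0, -15.0, -5.0, 5.0, 15.0, 30.0)
    candidates: list[BuiltModel] = []
    # restart 0 starts from the unperturbed graft, so the returned model is
    # never worse than a plain greedy minimization of the input
    for k in range(n_restarts):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, k])
        sampler = _TorsionSampler(model)
        if k > 0:
            for ridx in range(len(sampler.rotatable)):
                kick = float(rng.normal(0.0, sigma_deg))
                sampler.try_chi(ridx, sampler.chi_value(ridx) + kick)
        coarse_first = 0 < k <= n_restarts // 2
        if coarse_first:
            for ridx in range(len(sampler.rotatable)):
                scores = []
                for ang in np.arange(-180.0, 180.0, 30.0):
                    scores.append((sampler.try_chi(ridx, float(ang)), float(ang)))
                best = min(scores, key=lambda t: t[0])
                sampler.try_chi(ridx, best[1])
        for _ in range(max_sweeps):
            improved = False
            for ridx in range(len(sampler.rotatable)):
                cur_val = sampler.chi_value(ridx)
                cur_sc = sampler.try_chi(ridx, cur_val)
                best_sc, best_val = cur_sc, cur_val
                for dlt in fine_deltas:
                    sc = sampler.try_chi(ridx, cur_val + dlt)
                    if sc < best_sc - 1e-12:
                        best_sc, best_val = sc, cur_val + dlt
                sampler.try_chi(ridx, best_val)
                if best_sc < cur_sc - 1e-12:
                    improved = True
            if not improved:
                break
        candidates.append(as_model(sampler.structure, sampler.total_score()))

    candidates.sort(key=lambda m: m.clash_score)
    if return_candidates:
        return candidates
    return candidates[0]


def select_final_model(candidates: list[BuiltModel], mep: MEP, *,
                       desired_state: str = "out",
                       probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS,
                       radius_set: str = DEFAULT_RADIUS_TABLE,
                       ratio_hi: float = RATIO_HI,
                       ratio_lo: float = RATIO_LO) -> BuiltModel:
    """Pick the final model: desired mutant exposure first, lowest clash second.

    Candidates are examined in ascending clash order and the first whose
    mutated residue carries the desired buried/exposed flag wins; with
    ``desired_state='any'`` (or when no candidate matches, with a warning)
    the lowest-score model is returned.
    """
    if not candidates:
        raise ValueError("no candidate models")
    if desired_state not in ("out", "in", "any"):
        raise ValueError("desired_state must be out/in/any")
    ordered = sorted(candidates, key=lambda m: m.clash_score)

    def flag_of(m: BuiltModel) -> str:
        s = m.structure
        report = residue_sasa(s, s.peptide_chain, probe, n_points, radius_set)
        report = annotate_in_out(report, ratio_hi, ratio_lo)
        m.mutant_flag = report.row_for(mep.mutant_pos).flag
        return m.mutant_flag

    if desired_state == "any":
        best = ordered[0]
        flag_of(best)
        return best
    for m in ordered:
        if flag_of(m) == desired_state:
            return m
    best = ordered[0]
    best.warning = (f"no candidate with mutant residue {desired_state!r}; "
                    "returning lowest-clash model")
    return best
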