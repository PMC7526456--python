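"""Optimal rigid-body superposition (Kabsch) and C-alpha RMSD.

The rotation is the proper (determinant +1) least-squares minimizer; the
SVD solve is delegated to :class:`scipy.spatial.transform.Rotation`.
:func:`ca_rmsd` reproduces the usual modeling-quality readout for
peptide-MHC complexes: superpose on the MHC heavy-chain C-alpha trace
(the groove frame) and report the RMSD over the peptide C-alpha atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Structure


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3 proper rotation
    translation: np.ndarray    # 3-vector, A
    rmsd: float                # A
    n_atoms: int
    selection: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray, selection: str = "") -> SuperpositionResult:
    """Least-squares rigid transform mapping point set *P* onto *Q*.

    Reflections are excluded; degenerate (e.g. collinear) inputs still
    return a valid minimizer.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching N x 3 arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Q - qc, P - pc)
    R = rot.as_matrix()
    t = qc - R @ pc
    rmsd = float(rssd / np.sqrt(len(P)))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms=len(P), selection=selection)


def _paired_ca(model: Structure, template: Structure, chain_m: str,
               chain_t: str) -> tuple[np.ndarray, np.ndarray]:
    rm, rt = model.chains[chain_m], template.chains[chain_t]
    if len(rm) != len(rt):
        only_m = [f"{r.name}{r.seq_id}" for r in rm[len(rt):]]
        only_t = [f"{r.name}{r.seq_id}" for r in rt[len(rm):]]
        raise ValueError(
            f"cannot pair chains {chain_m!r}/{chain_t!r}: unmatched residues "
            f"{only_m or only_t}")
    has_ca_m = [r.has_atom("CA") for r in rm]
    has_ca_t = [r.has_atom("CA") for r in rt]
    if any(has_ca_m) or any(has_ca_t):
        if has_ca_m != has_ca_t:
            raise ValueError(
                f"cannot pair chains {chain_m!r}/{chain_t!r}: CA atoms present "
                "in different residues")
        P = np.array([r.atom("CA").coords for r in rm if r.has_atom("CA")])
        Q = np.array([r.atom("CA").coords for r in rt if r.has_atom("CA")])
        return P, Q
    # no CA at all (e.g. pseudo-atom scaffolds): pair every atom by order
    P = np.array([a.coords for r in rm for a in r.atoms])
    Q = np.array([a.coords for r in rt for a in r.atoms])
    if len(P) != len(Q):
        raise ValueError(
            f"cannot pair chains {chain_m!r}/{chain_t!r}: atom counts differ")
    return P, Q


def ca_rmsd(model: Structure, template: Structure,
            align_on: str = "mhc") -> float:
    """Peptide C-alpha RMSD of *model* against *template*.

    *align_on* selects the superposition atoms: ``mhc`` (default, groove
    frame), ``peptide``, or ``all``.  The reported RMSD is always over the
    peptide C-alpha atoms after that superposition.
    """
    if align_on not in ("mhc", "peptide", "all"):
        raise ValueError("align_on must be one of mhc/peptide/all")
    if model.peptide_chain is None or template.peptide_chain is None:
        raise ValueError("both structures need peptide_chain set")
    pep_m, pep_t = _paired_ca(model, template, model.peptide_chain,
                              template.peptide_chain)
    if align_on == "peptide":
        return kabsch(pep_m, pep_t).rmsd
    if align_on == "mhc":
        if model.mhc_chain is None or template.mhc_chain is None:
            raise ValueError("align_on='mhc' needs mhc_chain set on both structures")
        ref_m, ref_t = _paired_ca(model, template, model.mhc_chain,
                                  template.mhc_chain)
    else:  # all: every chain paired by id
        if sorted(model.chains) != sorted(template.chains):
            raise ValueError("align_on='all' needs identical chain ids")
        parts = [_paired_ca(model, template, cid, cid) for cid in model.chains]
        ref_m = np.vstack([p[0] for p in parts])
        ref_t = np.vstack([p[1] for p in parts])
    sup = kabsch(ref_m, ref_t, selection=f"CA:{align_on}")
    moved = sup.apply(pep_m)
    return float(np.sqrt(((moved - pep_t) ** 2).sum(axis=1).mean()))
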