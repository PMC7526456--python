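"""Template selection: rank candidate peptide-MHC structures by sequence
similarity to a MEP and annotate/filter by mutant-position solvent exposure.

A live structure-database search is deliberately out of scope; candidates
come from a user-supplied set (a manifest TSV naming PDB files, or
structures already in memory).  Two scoring modes are shipped because
percent values reported for short epitopes are usually plain identity
fractions, but similarity counting (identical or positive
substitution-matrix score) is also common:

``identity``
    matched positions are exact matches (default);
``blosum``
    matched positions are exact matches or BLOSUM62-positive pairs.

Both scores are ungapped: when lengths differ, every offset of the shorter
sequence inside the longer is scored and the best is kept; the percentage
is over the shorter length.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd
from Bio.Align import substitution_matrices

from .chem import DEFAULT_RADIUS_TABLE, STANDARD_AA1
from .epitopes import MEP
from .sasa import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
    RATIO_HI,
    RATIO_LO,
    annotate_in_out,
    residue_sasa,
)
from .structure import Structure, assign_radii, read_pdb

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
SIMILARITY_MODES = ("identity", "blosum")


def _check_seq(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    if len(seq) > 15:
        raise ValueError(f"{what} sequence longer than 15 residues")
    bad = set(seq) - STANDARD_AA1
    if bad:
        raise ValueError(f"{what} sequence has invalid letters: {sorted(bad)}")
    return seq


def _position_match(x: str, y: str, mode: str) -> bool:
    if x == y:
        return True
    return mode == "blosum" and _BLOSUM62[x, y] > 0


def best_alignment(a: str, b: str, mode: str = "identity") -> tuple[float, int]:
    """Best ungapped alignment of *a* against *b*.

    Returns ``(percent, shift)`` where position ``i`` of *a* (0-based)
    aligns with position ``i + shift`` of *b*.  The shorter sequence is
    always fully covered by the longer; equal lengths admit only shift 0.
    """
    a = _check_seq(a, "query")
    b = _check_seq(b, "subject")
    if mode not in SIMILARITY_MODES:
        raise ValueError(f"mode must be one of {SIMILARITY_MODES}")
    la, lb = len(a), len(b)
    shifts = range(0, lb - la + 1) if lb >= la else range(lb - la, 1)
    best = (-1.0, 0)
    for s in shifts:
        n = sum(1 for i in range(la)
                if 0 <= i + s < lb and _position_match(a[i], b[i + s], mode))
        pct = 100.0 * n / min(la, lb)
        if pct > best[0]:
            best = (pct, s)
    return best


def similarity(a: str, b: str, mode: str = "identity") -> float:
    """Percent sequence similarity between two short peptides (0-100)."""
    return best_alignment(a, b, mode)[0]


@dataclass
class TemplateEntry:
    """A candidate template: structure plus bookkeeping."""

    template_id: str
    allele: str
    peptide_chain: str | None = None
    structure: Structure | None = None
    path: str | None = None

    def load(self, radius_set: str = DEFAULT_RADIUS_TABLE) -> Structure:
        if self.structure is None:
            if self.path is None:
                raise ValueError(f"template {self.template_id}: no structure or path")
            with open(self.path) as fh:
                s = read_pdb(fh.read(), peptide_chain=self.peptide_chain,
                             structure_id=self.template_id)
            self.structure = assign_radii(s, radius_set)
        if self.peptide_chain is None:
            self.peptide_chain = self.structure.peptide_chain
        if self.peptide_chain is None:
            raise ValueError(f"template {self.template_id}: peptide chain unknown")
        return self.structure

    def peptide_sequence(self) -> str:
        s = self.load()
        return s.sequence(self.peptide_chain)


@dataclass
class TemplateHit:
    template_id: str
    peptide_seq: str
    similarity: float               # percent, 0-100
    mutant_exposure: str            # in / out / unassigned
    allele: str
    shift: int = 0                  # MEP->template position offset (0-based)
    entry: TemplateEntry | None = None
    warning: str | None = None


def read_manifest(path: str) -> list[TemplateEntry]:
    """Template manifest TSV: columns template_id, path, allele, peptide_chain.

    Relative paths resolve against the manifest's directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"template_id", "path", "allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))
    entries = []
    for rec in df.to_dict("records"):
        p = rec["path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        pc = rec.get("peptide_chain")
        entries.append(TemplateEntry(template_id=rec["template_id"], path=p,
                                     allele=rec["allele"],
                                     peptide_chain=None if pd.isna(pc) else pc))
    return entries


def rank_templates(mep: MEP, db: list[TemplateEntry], *,
                   mode: str = "identity",
                   probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_N_POINTS,
                   radius_set: str = DEFAULT_RADIUS_TABLE,
                   ratio_hi: float = RATIO_HI,
                   ratio_lo: float = RATIO_LO) -> list[TemplateHit]:
    """Score every allele-matching candidate and sort best-first.

    Ordering is by similarity descending, ties broken by template_id
    ascending (total and deterministic).  Each hit carries the
    buried/exposed state of the template residue aligned with the MEP's
    mutant position, computed on the template structure itself.
    """
    candidates = [e for e in db if e.allele == mep.allele]
    if not candidates:
        raise ValueError(f"no templates for allele {mep.allele}")
    hits = []
    for entry in candidates:
        seq = entry.peptide_sequence()
        pct, shift = best_alignment(mep.sequence, seq, mode)
        tpl_pos = mep.mutant_pos + shift          # 1-based in template peptide
        if 1 <= tpl_pos <= len(seq):
            struct = entry.load(radius_set)
            report = residue_sasa(struct, entry.peptide_chain, probe, n_points,
                                  radius_set)
            report = annotate_in_out(report, ratio_hi, ratio_lo)
            exposure = report.row_for(tpl_pos).flag
        else:
            exposure = "unassigned"
        hits.append(TemplateHit(template_id=entry.template_id, peptide_seq=seq,
                                similarity=pct, mutant_exposure=exposure,
                                allele=entry.allele, shift=shift, entry=entry))
    hits.sort(key=lambda h: (-h.similarity, h.template_id))
    return hits


def select_final(ranked: list[TemplateHit],
                 desired_state: str = "out") -> TemplateHit:
    """Highest-similarity hit whose mutant-position exposure matches.

    Mirrors the template-choice rule of exposure-aware homology modeling:
    among near-equal-similarity candidates, prefer the one presenting the
    mutated residue in the *desired* solvent state.  If no hit matches,
    the overall best hit is returned with a warning attached.
    """
    if not ranked:
        raise ValueError("empty ranked template list")
    if desired_state not in ("out", "in", "any"):
        raise ValueError("desired_state must be out/in/any")
    if desired_state != "any":
        for hit in ranked:
            if hit.mutant_exposure == desired_state:
                return hit
        top = ranked[0]
        top.warning = (f"no template with mutant residue {desired_state!r}; "
                       f"falling back to {top.template_id}")
        return top
    return ranked[0]
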