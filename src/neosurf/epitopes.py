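"""Minimal epitope peptides (MEPs) and register-shuffled variants.

A MEP is the 8-10 residue peptide actually presented in the MHC class I
groove, carrying a single tumor mutation at a known 1-based position.
Shuffle variants slide the presented window along the longer protein
context so that the mutated residue lands at a different position of the
peptide — the operation that, in the groove, can move a mutation from a
solvent-facing position into a buried one.

MEP sets round-trip through FASTA; the mutant position travels in the
header as ``pos=<k>`` and the allele as ``allele=<name>``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import STANDARD_AA1

ALLELES = ("H-2Kb", "H-2Db")


@dataclass(frozen=True)
class MEP:
    name: str
    sequence: str
    mutant_pos: int            # 1-based
    allele: str
    wild_aa: str | None = None

    @property
    def mutant_aa(self) -> str:
        return self.sequence[self.mutant_pos - 1]

    def __len__(self) -> int:
        return len(self.sequence)


def _check_sequence(seq: str, lo: int = 8, hi: int = 10) -> str:
    seq = seq.upper()
    bad = set(seq) - STANDARD_AA1
    if bad:
        raise ValueError(f"invalid amino-acid letters: {sorted(bad)}")
    if not lo <= len(seq) <= hi:
        raise ValueError(f"sequence length {len(seq)} outside [{lo}, {hi}]")
    return seq


def make_mep(name: str, sequence: str, mutant_pos: int, allele: str,
             wild_aa: str | None = None) -> MEP:
    """Validated minimal epitope peptide; mutant_aa is read off the sequence."""
    sequence = _check_sequence(sequence)
    if not 1 <= mutant_pos <= len(sequence):
        raise ValueError(f"mutant_pos {mutant_pos} out of range 1..{len(sequence)}")
    if allele not in ALLELES:
        raise ValueError(f"allele must be one of {ALLELES}")
    return MEP(name=name, sequence=sequence, mutant_pos=mutant_pos,
               allele=allele, wild_aa=wild_aa)


def shuffle_variants(context: str, mutant_context_pos: int,
                     window_lengths, target_positions,
                     allele: str = "H-2Kb",
                     name_prefix: str = "v") -> list[MEP]:
    """Windows of *context* that put the mutated residue at chosen positions.

    Every returned MEP is a contiguous substring of *context* whose length
    is in *window_lengths* and in which the mutant sits at one of
    *target_positions* (1-based within the window).  Duplicate
    (sequence, position) pairs are removed; order is by length then
    position.  An unsatisfiable request yields an empty list.
    """
    context = context.upper()
    bad = set(context) - STANDARD_AA1
    if bad:
        raise ValueError(f"invalid amino-acid letters in context: {sorted(bad)}")
    if not 1 <= mutant_context_pos <= len(context):
        raise ValueError("mutant_context_pos outside context")
    out: list[MEP] = []
    seen: set[tuple[str, int]] = set()
    counter = 0
    for length in sorted(set(int(x) for x in window_lengths)):
        for pos in sorted(set(int(x) for x in target_positions)):
            if not 1 <= pos <= length:
                continue
            start = mutant_context_pos - pos  # 0-based window start
            if start < 0 or start + length > len(context):
                continue
            seq = context[start:start + length]
            if (seq, pos) in seen:
                continue
            seen.add((seq, pos))
            counter += 1
            out.append(make_mep(f"{name_prefix}{counter}", seq, pos, allele))
    return out


def write_fasta(meps: list[MEP], path_or_buffer) -> None:
    records = []
    for m in meps:
        desc = f"pos={m.mutant_pos} allele={m.allele}"
        if m.wild_aa:
            desc += f" wild={m.wild_aa}"
        records.append(SeqRecord(Seq(m.sequence), id=m.name, description=desc))
    if isinstance(path_or_buffer, (str,)):
        with open(path_or_buffer, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, path_or_buffer, "fasta")


def read_fasta(path_or_buffer) -> list[MEP]:
    """Read a MEP set; headers must carry ``pos=<k>`` and may carry ``allele=``."""
    if isinstance(path_or_buffer, str):
        handle: io.TextIOBase = open(path_or_buffer)
    else:
        handle = path_or_buffer
    try:
        meps = []
        for rec in SeqIO.parse(handle, "fasta"):
            fields = dict(tok.split("=", 1) for tok in rec.description.split()
                          if "=" in tok)
            if "pos" not in fields:
                raise ValueError(f"record {rec.id}: header lacks pos=<k>")
            meps.append(make_mep(rec.id, str(rec.seq), int(fields["pos"]),
                                 fields.get("allele", "H-2Kb"),
                                 wild_aa=fields.get("wild")))
        return meps
    finally:
        if isinstance(path_or_buffer, str):
            handle.close()
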