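"""Register shuffling: moving the mutation within the presented window.

Slides 8- and 9-residue windows over a protein context so that the
mutated serine lands at different peptide positions — the computational
counterpart of testing epitope variants that bury or expose the mutation.
"""

from neosurf import shuffle_variants

# 20-mer context with the mutated Ser at position 11
context = "AAAAASLFNLSMGKLAAAAA"

variants = shuffle_variants(context, mutant_context_pos=11,
                            window_lengths={8, 9},
                            target_positions={4, 5, 6},
                            allele="H-2Kb")
print(f"{'len':>3} {'pos':>3} sequence")
for m in variants:
    marked = (m.sequence[:m.mutant_pos - 1] + "[" + m.mutant_aa + "]"
              + m.sequence[m.mutant_pos:])
    print(f"{len(m.sequence):>3} {m.mutant_pos:>3} {marked}")
# The length-8 window with the Ser at position 4 is the original epitope
# FNLSMGKL; positions 5 and 6 give the shifted variants LFNLSMGK and
# SLFNLSMGK, which present the same mutation at different groove positions.
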