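# neosurf

Structural analysis of minimal neoepitopes presented by MHC class I.

Tumor neoantigen vaccines are built from *minimal epitope peptides*
(MEPs): 8–10-residue peptides carrying a single tumor mutation, presented
in the groove of an MHC class I molecule. Binding-affinity predictors
select such peptides, but binding alone predicts T-cell immunogenicity
poorly — the T-cell receptor must also *see* the mutated residue, which it
can only do if the mutant side chain points out of the groove toward
solvent. `neosurf` implements the structural side of that argument as a
reusable, fully tested pipeline for researchers triaging candidate
neoepitopes:

- **SASA engine** — per-residue solvent-accessible surface area by
  Shrake–Rupley quadrature on a deterministic spiral point set, decomposed
  into backbone / side-chain / apolar contributions, with each residue
  annotated buried (`in`) or solvent-exposed (`out`) from its relative
  side-chain exposure against an extended Gly-X-Gly reference;
- **superposition** — Kabsch least-squares rigid alignment and peptide
  Cα RMSD in the groove frame;
- **template selection** — ranking of candidate peptide–MHC structures by
  ungapped percent identity (or BLOSUM62 similarity) to the MEP, filtered
  by the solvent state of the residue aligned with the mutation;
- **model builder** — grafting of the MEP sequence onto the selected
  template's peptide backbone with ideal side-chain geometry, followed by
  seeded multi-restart torsion refinement against a soft-sphere clash
  score;
- **epitope operations** — register shuffling: sliding the presented
  window along the protein context so the mutation lands at a different
  peptide position;
- **predictor** — the immunogenicity decision rule combining the mutant
  residue's absolute side-chain SASA (immunogenic above 20 Å², nonimmunogenic
  below 15 Å²) with its in/out orientation; disagreements and the 15–20 Å²
  gray zone are reported `indeterminate`;
- **synthetic data** — a parameterized toy groove (packed floor slab,
  flanking walls, peptide with per-position up/down side chains) with
  generation-time ground truth, so every stage is testable without any
  structure download.

## The decision rule

For a MEP modeled in the groove, let `A_sc` be the side-chain SASA of the
mutated residue and let its orientation flag be `out` if
`A_sc / A_ref(X) > 50 %` and `in` if `< 20 %`, where `A_ref(X)` is the
side-chain area of residue type X in an extended Gly-X-Gly tripeptide.
Then

    immunogenic      if  A_sc > 20 Å²  and  flag ≠ in
    nonimmunogenic   if  A_sc < 15 Å²  and  flag ≠ out
    indeterminate    otherwise

## Worked example

```python
from neosurf import (PipelineConfig, make_mep, make_template_set,
                     run_pipeline)

mep = make_mep("77-5", "FNLSMGKL", mutant_pos=4, allele="H-2Kb")
db, _ = make_template_set(3, mep, [62.5, 50.0, 37.5], seed=2,
                          exposures=["out", "out", "in"])
pred = run_pipeline(mep, db, PipelineConfig(n_restarts=20, n_points=480,
                                            seed=1))
print(pred.mutant_sasa, pred.flag, pred.call)
```

Running `python examples/04_build_and_predict.py` (which wraps the above
plus the buried variant route) prints:

```
77-5: mutant S4 SASA 68.91 A^2, out -> immunogenic
77-5v1: mutant S5 SASA 0.00 A^2, in -> nonimmunogenic
```

The mutated serine of `FNLSMGKL` sits on a solvent-facing groove position
(side-chain SASA 68.9 Å², well above the 20 Å² threshold) and the peptide
is called immunogenic; shifting the window by one residue (`LFNLSMGK`)
moves the same serine onto a buried position (SASA ≈ 0 Å²) and the call
flips to nonimmunogenic. The other scripts in `examples/` demonstrate the
SASA report, groove ground-truth recovery, exposure-aware template
selection and register shuffling, one capability each.

A thin CLI mirrors the library (`neosurf sasa / superpose / shuffle /
build / predict / simulate`); see `neosurf --help`.

## Layout

```
src/neosurf/     structure.py  sasa.py  superpose.py  templates.py
                 builder.py    epitopes.py  predict.py  synthetic.py
                 peptides.py   chem.py  config.py  cli.py
tests/           unit + property + acceptance suites (pytest, hypothesis)
examples/        one narrative script per capability
docs/methods.md  models, parameters, numerical choices, limitations
```
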