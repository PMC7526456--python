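"""End-to-end immunogenicity prediction for a MEP.

Runs the full pipeline — template ranking, exposure-aware selection,
backbone grafting, seeded clash refinement, per-residue SASA and the
SASA/orientation decision rule — for an exposed-mutant peptide and for
its register-shifted variant whose mutation lands on a buried position.
"""

from neosurf import PipelineConfig, make_mep, make_template_set, run_pipeline

cfg = PipelineConfig(n_restarts=20, n_points=480, seed=1)

# exposed route: mutated Ser at position 4, template presents it to solvent
mep = make_mep("77-5", "FNLSMGKL", mutant_pos=4, allele="H-2Kb")
db, _ = make_template_set(3, mep, [62.5, 50.0, 37.5], seed=2,
                          exposures=["out", "out", "in"])
pred = run_pipeline(mep, db, cfg)
print(f"{mep.name}: mutant {mep.mutant_aa}{mep.mutant_pos} "
      f"SASA {pred.mutant_sasa:.2f} A^2, {pred.flag} -> {pred.call}")

# buried route: one-position shuffle buries the Ser
variant = make_mep("77-5v1", "LFNLSMGK", mutant_pos=5, allele="H-2Kb")
db2, _ = make_template_set(3, variant, [50.0, 37.5, 25.0], seed=3,
                           exposures=["in", "in", "out"])
cfg2 = PipelineConfig(n_restarts=20, n_points=480, seed=1,
                      desired_exposure="in")
pred2 = run_pipeline(variant, db2, cfg2)
print(f"{variant.name}: mutant {variant.mutant_aa}{variant.mutant_pos} "
      f"SASA {pred2.mutant_sasa:.2f} A^2, {pred2.flag} -> {pred2.call}")
# A mutant side-chain SASA above 20 A^2 with an outward orientation is
# called immunogenic; below 15 A^2 with a buried orientation,
# nonimmunogenic; anything between or conflicting stays indeterminate.
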