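"""Immunogenicity classification and the end-to-end pipeline.

The decision rule combines the two structural readouts of the mutated
residue in the modeled groove complex:

* its absolute side-chain SASA against two thresholds (immunogenic above
  ``hi`` = 20 A^2, nonimmunogenic below ``lo`` = 15 A^2), and
* its buried/exposed orientation flag.

A call is made only when both pieces of evidence agree (the flag may be
"unassigned"); SASA values in the [lo, hi] gray zone or a SASA/flag
conflict yield "indeterminate" rather than a forced binary call.  The
classifier predicts a structural propensity for T-cell recognition; it
says nothing about actual T-cell assays.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

from .builder import graft_peptide, refine, select_final_model
from .config import PipelineConfig
from .epitopes import MEP
from .sasa import annotate_in_out, residue_sasa
from .structure import write_pdb
from .templates import TemplateEntry, rank_templates, select_final

logger = logging.getLogger("neosurf.pipeline")

CALLS = ("immunogenic", "nonimmunogenic", "indeterminate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class Prediction:
    mep: MEP
    mutant_sasa: float          # side-chain SASA of the mutated residue, A^2
    flag: str                   # in / out / unassigned
    call: str                   # immunogenic / nonimmunogenic / indeterminate
    sasa_hi: float = 20.0
    sasa_lo: float = 15.0
    evidence: dict | None = None

    def to_json(self, **kwargs) -> str:
        data = asdict(self)
        data["mep"] = {"name": self.mep.name, "sequence": self.mep.sequence,
                       "mutant_pos": self.mep.mutant_pos,
                       "mutant_aa": self.mep.mutant_aa, "allele": self.mep.allele}
        return json.dumps(data, **kwargs)


def classify(mutant_sasa: float, flag: str, hi: float = 20.0,
             lo: float = 15.0) -> str:
    """Immunogenicity call from mutant-residue SASA and orientation."""
    if mutant_sasa < 0:
        raise ValueError("negative SASA")
    if not lo < hi:
        raise ValueError("require lo < hi")
    if flag not in ("in", "out", "unassigned"):
        raise ValueError(f"invalid flag {flag!r}")
    if mutant_sasa > hi and flag in ("out", "unassigned"):
        return "immunogenic"
    if mutant_sasa < lo and flag in ("in", "unassigned"):
        return "nonimmunogenic"
    return "indeterminate"


def run_pipeline(mep: MEP, template_db: list[TemplateEntry],
                 config: PipelineConfig | None = None) -> Prediction:
    """Template choice -> graft -> refine -> SASA -> classification.

    Deterministic given (inputs, ``config.seed``).  When
    ``config.out_dir`` is set, the intermediate artifacts (selected
    template, model PDB, per-residue SASA TSV, prediction JSON) are
    written there.
    """
    cfg = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        logger.info("stage %s done", name)
        return out

    ranked = stage("rank_templates", rank_templates, mep, template_db,
                   mode=cfg.similarity_mode, probe=cfg.probe,
                   n_points=cfg.n_points, radius_set=cfg.radius_set,
                   ratio_hi=cfg.ratio_hi, ratio_lo=cfg.ratio_lo)
    hit = stage("select_final", select_final, ranked, cfg.desired_exposure)
    logger.info("template %s (similarity %.1f%%, mutant %s)",
                hit.template_id, hit.similarity, hit.mutant_exposure)
    template = hit.entry.load(cfg.radius_set)
    model0 = stage("graft_peptide", graft_peptide, template, mep,
                   trim=cfg.graft_trim, radius_set=cfg.radius_set)
    candidates = stage("refine", refine, model0, cfg.n_restarts, cfg.seed,
                       sigma_deg=cfg.perturb_sigma_deg, template=template,
                       template_id=hit.template_id, return_candidates=True)
    final = stage("select_final_model", select_final_model, candidates, mep,
                  desired_state=cfg.desired_exposure, probe=cfg.probe,
                  n_points=cfg.n_points, radius_set=cfg.radius_set,
                  ratio_hi=cfg.ratio_hi, ratio_lo=cfg.ratio_lo)

    s = final.structure
    report = stage("residue_sasa", residue_sasa, s, s.peptide_chain,
                   cfg.probe, cfg.n_points, cfg.radius_set)
    report = stage("annotate_in_out", annotate_in_out, report,
                   cfg.ratio_hi, cfg.ratio_lo)
    row = report.row_for(mep.mutant_pos)
    call = stage("classify", classify, row.sidechain, row.flag,
                 cfg.sasa_hi, cfg.sasa_lo)
    prediction = Prediction(
        mep=mep, mutant_sasa=row.sidechain, flag=row.flag, call=call,
        sasa_hi=cfg.sasa_hi, sasa_lo=cfg.sasa_lo,
        evidence={
            "template_id": hit.template_id,
            "template_similarity": hit.similarity,
            "template_mutant_exposure": hit.mutant_exposure,
            "template_warning": hit.warning,
            "clash_score": final.clash_score,
            "ca_rmsd_to_template": final.ca_rmsd_to_template,
            "n_restarts": final.n_restarts,
            "seed": final.seed,
            "exposure_ratio_pct": row.ratio,
            "model_warning": final.warning,
        })

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        prefix = os.path.join(cfg.out_dir, mep.name.replace("/", "_"))
        with open(f"{prefix}_model.pdb", "w") as fh:
            fh.write(write_pdb(s))
        report.write_tsv(f"{prefix}_sasa.tsv")
        with open(f"{prefix}_prediction.json", "w") as fh:
            fh.write(prediction.to_json(indent=2))
        with open(f"{prefix}_template.json", "w") as fh:
            json.dump({"template_id": hit.template_id,
                       "similarity": hit.similarity,
                       "mutant_exposure": hit.mutant_exposure,
                       "warning": hit.warning}, fh, indent=2)
    return prediction
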