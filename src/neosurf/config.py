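"""Flat key-value configuration for the prediction pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .chem import DEFAULT_RADIUS_TABLE


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, in one flat record.

    SASA quadrature: ``probe`` (A, water = 1.4) and ``n_points`` per atom.
    Annotation: relative side-chain exposure cutoffs ``ratio_hi`` /
    ``ratio_lo`` (percent; out above, in below).  Classification: absolute
    mutant side-chain SASA thresholds ``sasa_hi`` / ``sasa_lo`` (A^2).
    Template choice: ``similarity_mode`` (identity or blosum) and
    ``desired_exposure`` (out / in / any) for the mutant position.
    Refinement: ``n_restarts`` seeded restarts, Gaussian chi kick
    ``perturb_sigma_deg``.  ``seed`` drives every random draw.
    """

    probe: float = 1.4
    n_points: int = 960
    radius_set: str = DEFAULT_RADIUS_TABLE
    ratio_hi: float = 50.0
    ratio_lo: float = 20.0
    sasa_hi: float = 20.0
    sasa_lo: float = 15.0
    similarity_mode: str = "identity"
    desired_exposure: str = "out"
    n_restarts: int = 200
    perturb_sigma_deg: float = 20.0
    graft_trim: str = "cterm"
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
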