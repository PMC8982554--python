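"""Pipeline-wide thresholds and geometry parameters.

All distances are in base pairs; all q-value and correlation thresholds are
dimensionless. The defaults are the thresholds used throughout the analysis:
a feature must be expressed in at least 10% of a cohort's tumor or normal
samples to be testable, differential expression requires |log2FC| >= 1 at
BH q < 0.05, promoters span 0.5 kb upstream to 1 kb downstream of the TSS,
candidate target genes lie within +/-100 kb of the enhancer center and are
screened at Spearman corr >= 0.3 / q < 0.05, and SNPs are mapped into
enhancers extended by 0.5 kb on each side.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    prevalence_min: float = 0.10
    expressed_threshold: float = 0.0
    log2fc_min: float = 1.0
    q_max: float = 0.05
    promoter_upstream: int = 500
    promoter_downstream: int = 1000
    link_window: int = 100_000
    corr_min: float = 0.3
    link_q_max: float = 0.05
    snp_flank: int = 500
    tfbs_p_max: float = 1e-4
    pseudocount: float = 0.01
    seed: int = 0
    # statistic variants (defaults documented in docs/methods.md)
    t_test: str = "welch"          # "welch" | "student"
    link_samples: str = "tumor"    # "tumor" | "all"
    corr_mode: str = "positive"    # "positive" | "abs"
    pfm_pseudocount: float = 0.8
    score_granularity: float = 1e-3  # bits per grid cell for the PWM null

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.prevalence_min <= 1.0):
            raise ValidationError("prevalence_min must be in [0, 1]")
        if self.expressed_threshold < 0:
            raise ValidationError("expressed_threshold must be >= 0")
        if self.log2fc_min < 0:
            raise ValidationError("log2fc_min must be >= 0")
        for name in ("q_max", "link_q_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("promoter_upstream", "promoter_downstream", "snp_flank"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.link_window <= 0:
            raise ValidationError("link_window must be > 0")
        if not (-1.0 <= self.corr_min <= 1.0):
            raise ValidationError("corr_min must be in [-1, 1]")
        if not (0.0 < self.tfbs_p_max <= 1.0):
            raise ValidationError("tfbs_p_max must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.pfm_pseudocount < 0:
            raise ValidationError("pfm_pseudocount must be >= 0")
        if self.score_granularity <= 0:
            raise ValidationError("score_granularity must be > 0")
        if self.t_test not in ("welch", "student"):
            raise ValidationError("t_test must be 'welch' or 'student'")
        if self.link_samples not in ("tumor", "all"):
            raise ValidationError("link_samples must be 'tumor' or 'all'")
        if self.corr_mode not in ("positive", "abs"):
            raise ValidationError("corr_mode must be 'positive' or 'abs'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - cls.field_names()
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat key: value file (YAML dialect)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain key: value pairs")
        return cls.from_dict(data)
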