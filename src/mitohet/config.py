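"""Pipeline configuration: every numeric threshold in one place.

Defaults equal the published values of the capture pipeline (error rate
0.02%, per-site Bonferroni alpha 0.01/16569, calling VAF floor 0.5%, depth
floor 100x with 70% of bases at BAQ >= 30, >= 5 minor alleles, log-likelihood
score >= 5, Fisher P >= 1e-4 with fold-change <= 5 and duplicate-stratum VAF
>= 0.2%, MAPQ >= 20 / BAQ >= 30 screens, mismatch caps 5 coding / 8 D-loop,
contamination flag at >= 11 polymorphic coding-region variants).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .caller import CallerThresholds, ErrorModel


@dataclass
class PipelineConfig:
    reference_fasta: str | None = None  # None -> bundled mini genome
    region_config: str | None = None
    shift_bp: int = 120
    n_segments: int = 46
    read_length: int = 250
    depth: float = 4000.0
    duplicate_rate: float = 0.5
    numts_fraction: float = 0.0
    baq_values: tuple[float, ...] = (30.0, 20.0)
    baq_probs: tuple[float, ...] = (0.9, 0.1)
    error_rate: float = 2e-4
    alpha: float = 0.01 / 16569
    thresholds: CallerThresholds = field(default_factory=CallerThresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.error_rate <= 0:
            raise ValueError("error rate must be positive")
        if not 1 <= self.n_segments:
            raise ValueError("n_segments must be >= 1")
        t = self.thresholds
        if isinstance(t, dict):
            self.thresholds = CallerThresholds(**t)
        for name in (
            "min_depth", "min_minor", "min_loglik", "min_fisher_p",
            "max_fold_change", "min_vaf_dup", "min_vaf", "min_baq",
        ):
            if getattr(self.thresholds, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @property
    def error_model(self) -> ErrorModel:
        return ErrorModel(per_base_error_rate=self.error_rate, alpha=self.alpha)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baq_values"] = list(d["baq_values"])
        d["baq_probs"] = list(d["baq_probs"])
        return d

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "baq_values" in data:
            data["baq_values"] = tuple(data["baq_values"])
        if "baq_probs" in data:
            data["baq_probs"] = tuple(data["baq_probs"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
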