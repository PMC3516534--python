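"""Run configuration: thresholds, input paths, seed; YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds; serialized into every output dir.

    Optional stage inputs left as None cause that stage to be skipped.
    """

    # required assembly inputs
    parts_a: str | None = None
    parts_b: str | None = None
    ppi: str | None = None
    complexes: str | None = None
    reactions: str | None = None
    pathways: str | None = None
    tissue_calls: str | None = None
    coexpr: str | None = None
    # optional stage inputs
    gmt: str | None = None
    expression: str | None = None
    expression_labels: str | None = None
    sumstats: str | None = None
    annotation: str | None = None
    annotation_dialect: str = "tsv"
    trait_sumstats: str | None = None
    catalog_snps: str | None = None
    # thresholds
    lab_count_min: int = 2
    corr_method: str = "pearson"
    corr_fdr_alpha: float = 0.05
    min_evidence: int = 3
    min_overlap: int = 10
    alpha: float = 0.05
    window_bp: int = 500_000
    catalog_window_bp: int = 250_000
    percentile_cutoff: float = 0.95
    n_sim: int = 10_000
    n_perm: int = 1000
    risk_weighting: str = "ivw"
    seed: int = 0

    def validate(self) -> None:
        if self.lab_count_min < 1:
            raise ValueError("lab_count_min must be >= 1")
        if not (0 < self.corr_fdr_alpha < 1) or not (0 < self.alpha < 1):
            raise ValueError("alpha thresholds must be in (0, 1)")
        if not (0 < self.percentile_cutoff < 1):
            raise ValueError("percentile_cutoff must be in (0, 1)")
        if self.window_bp < 0 or self.catalog_window_bp < 0:
            raise ValueError("windows must be >= 0")
        if self.min_evidence < 1 or self.min_overlap < 0:
            raise ValueError("min_evidence must be >= 1 and min_overlap >= 0")
        if self.n_sim < 1 or self.n_perm < 100:
            raise ValueError("n_sim must be >= 1 and n_perm >= 100")
        if self.corr_method not in {"pearson", "spearman"}:
            raise ValueError(f"unknown corr_method {self.corr_method!r}")
        if self.risk_weighting not in {"ivw", "inv_se"}:
            raise ValueError(f"unknown risk_weighting {self.risk_weighting!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable short hash of the full configuration."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def header_comment(self) -> str:
        return f"# config_hash={self.digest()} seed={self.seed}\n"
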