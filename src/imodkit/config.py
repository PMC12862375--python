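"""Pipeline configuration: a flat, versioned, YAML-serializable parameter set."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "QcConfig", "IcaConfig", "MembershipConfig",
           "EnrichmentConfig", "DimaConfig", "CompareConfig"]

CONFIG_VERSION = 1


@dataclass
class QcConfig:
    min_reads: int = 500_000
    min_replicate_r: float = 0.95


@dataclass
class IcaConfig:
    dimension_grid: list[int] = field(default_factory=lambda: [5, 10, 15, 20])
    n_runs: int = 100
    cluster_eps: float = 0.1
    min_frequency: float = 0.5


@dataclass
class MembershipConfig:
    k2_cutoff: float = 550.0
    dominance_ratio: float = 5.0


@dataclass
class EnrichmentConfig:
    q_threshold: float = 1e-5
    max_regulators: int = 2


@dataclass
class DimaConfig:
    min_delta: float = 5.0
    alpha: float = 0.05
    min_pairs: int = 10
    pooled_null: bool = False


@dataclass
class CompareConfig:
    min_r: float = 0.5
    use_absolute_r: bool = False


@dataclass
class PipelineConfig:
    expression: str = ""
    metadata: str = ""
    trn: str = ""
    outdir: str = "imodkit_out"
    seed: int = 0
    qc: QcConfig = field(default_factory=QcConfig)
    ica: IcaConfig = field(default_factory=IcaConfig)
    membership: MembershipConfig = field(default_factory=MembershipConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    dima: DimaConfig = field(default_factory=DimaConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if not 0 <= self.dima.alpha <= 1:
            raise ValueError("dima.alpha must be in [0, 1]")
        if not 0 <= self.enrichment.q_threshold <= 1:
            raise ValueError("enrichment.q_threshold must be in [0, 1]")
        if not 0 < self.ica.min_frequency <= 1:
            raise ValueError("ica.min_frequency must be in (0, 1]")
        if self.ica.cluster_eps <= 0:
            raise ValueError("ica.cluster_eps must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key, sub in [
            ("qc", QcConfig), ("ica", IcaConfig), ("membership", MembershipConfig),
            ("enrichment", EnrichmentConfig), ("dima", DimaConfig), ("compare", CompareConfig),
        ]:
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def sha256(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()
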