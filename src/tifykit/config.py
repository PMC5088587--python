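"""Pipeline configuration: one auditable home for every numeric setting.

The defaults are the analysis settings of the study design: orthologue
thresholds E < 1e-10 / score > 200 / positives > 70%, paralogue thresholds
E < 1e-50 / score > 200 / positives > 80%, RPKM fold-change threshold 2,
log2-RPKM level bins [1, 4], synonymous clock rate 6.5e-9 /site/year and
1,000 bootstrap iterations.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .homology import HomologyThresholds
from .molevol import DEFAULT_LAMBDA


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "tifykit_out"
    # optional explicit input paths; stages fall back to the simulate stage's
    # output layout under ``outdir``
    inputs: dict = field(default_factory=dict)
    # overrides for the synthetic-data generator (scalar fields of
    # FamilySimConfig; the generator seed always follows ``seed``)
    sim: dict = field(default_factory=dict)
    ortholog_thresholds: tuple = (1e-10, 200.0, 70.0)
    paralog_thresholds: tuple = (1e-50, 200.0, 80.0)
    evidence_identity_floor: float = 80.0
    fold_threshold: float = 2.0
    pseudocount: float = 0.01
    level_bins: tuple = (1.0, 4.0)
    lam: float = DEFAULT_LAMBDA
    bootstrap_replicates: int = 1000
    distance_model: str = "p_distance"

    def __post_init__(self) -> None:
        self.ortholog_thresholds = tuple(self.ortholog_thresholds)
        self.paralog_thresholds = tuple(self.paralog_thresholds)
        self.level_bins = tuple(self.level_bins)
        if self.distance_model not in ("p_distance", "poisson"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")

    @property
    def ortholog(self) -> HomologyThresholds:
        return HomologyThresholds(*self.ortholog_thresholds)

    @property
    def paralog(self) -> HomologyThresholds:
        return HomologyThresholds(*self.paralog_thresholds)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ortholog_thresholds"] = list(self.ortholog_thresholds)
        d["paralog_thresholds"] = list(self.paralog_thresholds)
        d["level_bins"] = list(self.level_bins)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
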