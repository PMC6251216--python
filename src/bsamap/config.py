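"""Pipeline configuration: one schema-checked object echoed into every output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import CrossDesign, PanelDesign, PoolDesign


@dataclass
class PipelineConfig:
    """All tunable thresholds and simulation designs of the pipeline.

    Defaults mirror the emulated study: 130 F2 individuals over 13
    chromosomes, an 822-accession diversity panel, a 50-individual
    recessive bulk, high-confidence variant QC (call count >= 100, minor
    allele frequency >= 0.1) and a +/-200 kb target interval.
    """

    cross: CrossDesign = field(default_factory=CrossDesign)
    panel: PanelDesign = field(default_factory=PanelDesign)
    pool: PoolDesign = field(default_factory=PoolDesign)
    qc_min_count: int = 100
    qc_min_freq: float = 0.1
    assoc_method: str = "chi2_genotypic"
    flank_bp: int = 200_000
    pool_min_depth: int = 10
    pool_min_alt_fraction: float = 0.95
    panel_rule: str = "no-allele"
    gene_flank_bp: int = 10_000
    splice_policy: str = "retain"
    #: size of the separate test F2 population the recessive bulk is drawn
    #: from (the mapping population itself is too small to supply 50
    #: recessive homozygotes)
    test_population_n_f2: int = 1231
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assoc_method not in ("chi2_genotypic", "glm_dosage_F"):
            raise ValueError(f"unknown association method {self.assoc_method!r}")
        if self.panel_rule not in ("no-allele", "no-homozygote"):
            raise ValueError(f"unknown panel rule {self.panel_rule!r}")
        if self.splice_policy not in ("retain", "cryptic-gt"):
            raise ValueError(f"unknown splice policy {self.splice_policy!r}")
        if self.flank_bp < 0 or self.gene_flank_bp < 0:
            raise ValueError("flanking distances must be non-negative")

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Derive a config whose every stochastic stage is seeded from ``seed``."""
        return dataclasses.replace(
            self,
            seed=seed,
            cross=dataclasses.replace(self.cross, seed=seed),
            panel=dataclasses.replace(self.panel, seed=seed + 1),
            pool=dataclasses.replace(self.pool, seed=seed + 2),
        )

    def to_dict(self) -> dict:
        return {
            "cross": dataclasses.asdict(self.cross),
            "panel": dataclasses.asdict(self.panel),
            "pool": dataclasses.asdict(self.pool),
            "qc_min_count": self.qc_min_count,
            "qc_min_freq": self.qc_min_freq,
            "assoc_method": self.assoc_method,
            "flank_bp": self.flank_bp,
            "pool_min_depth": self.pool_min_depth,
            "pool_min_alt_fraction": self.pool_min_alt_fraction,
            "panel_rule": self.panel_rule,
            "gene_flank_bp": self.gene_flank_bp,
            "splice_policy": self.splice_policy,
            "test_population_n_f2": self.test_population_n_f2,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, klass in (("cross", CrossDesign), ("panel", PanelDesign), ("pool", PoolDesign)):
            if key in data and isinstance(data[key], dict):
                data[key] = klass(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
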