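"""Pipeline configuration: one object, one YAML file, explicit defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .signal_finder import DEFAULT_PROMOTER_THRESHOLD, TerminatorParams
from .synthetic_data import SimConfig


class ConfigError(ValueError):
    """Raised for invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs.

    Either ``simulate`` is true (inputs are generated from ``sim``) or
    ``genome_fasta``/``annotation_gff``/``samples`` point at real inputs.
    Filtering defaults are the pipeline's canonical values: 40 bp IGR
    trimming, 120 bp minimum IGR length, 15% expression margin, |log2 FC|
    cutoff 1 and p cutoff 0.05.
    """

    outdir: str = "srna_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    genome_fasta: Optional[str] = None
    annotation_gff: Optional[str] = None
    samples: dict[str, str] = field(default_factory=dict)  # sample -> BED path
    control: str = "control"
    trim: int = 40
    min_len: int = 120
    margin: float = 0.15
    log2fc_cutoff: float = 1.0
    p_cutoff: float = 0.05
    promoter_threshold: float = DEFAULT_PROMOTER_THRESHOLD
    terminator: TerminatorParams = field(default_factory=TerminatorParams)
    target_seed_min: int = 8
    target_score_min: float = 10.0
    emit_fastq: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.terminator, dict):
            self.terminator = TerminatorParams(**self.terminator)

    def validate(self) -> None:
        if self.simulate:
            if self.control not in self.sim.conditions:
                raise ConfigError(
                    f"control sample {self.control!r} not among simulated "
                    f"conditions {list(self.sim.conditions)}"
                )
        else:
            if not (self.genome_fasta and self.annotation_gff and self.samples):
                raise ConfigError(
                    "non-simulated runs need genome_fasta, annotation_gff and samples"
                )
            if self.control not in self.samples:
                raise ConfigError(
                    f"control sample {self.control!r} not among samples "
                    f"{sorted(self.samples)}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg
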