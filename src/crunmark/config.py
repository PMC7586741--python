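"""Pipeline configuration with defaults matching the published analysis."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "SimulationConfig"]


@dataclass
class SimulationConfig:
    """Synthetic study layout: sizes, rates and planted structure."""

    n_contigs: int = 50
    mean_contig_len: int = 20_000
    n_genes: int = 100
    gene_len: int = 2000
    te_fraction: float = 0.1
    samples: tuple[str, ...] = ("EC_Ni", "EC_Id", "NEC_Ni", "NEC_Id", "seedling")
    marked_per_sample: int = 20
    enrichment_fold: float = 8.0
    background_rate: float = 0.01  # fragments per bp
    frag_len_mean: int = 170
    long_frac: float = 0.05
    n_tissues: int = 8
    n_specific: int = 25
    n_broad: int = 25
    n_go_terms: int = 30
    n_planted_terms: int = 2
    orphan_fraction: float = 0.2
    planted_odds: float = 8.0


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, defaulting to the published values.

    bin_size 500 bp; max_fragment 700 bp; fdr 1e-25; peak merge gap 100 bp;
    gene extension 500 bp; fold-change threshold 2; motif coverage
    threshold 8.0e-7 reads/total reads; motif merge gap 101 bp; natural-log
    entropy.
    """

    bin_size: int = 500
    max_fragment: int = 700
    fdr: float = 1e-25
    merge_gap: int = 100
    extension: int = 500
    fold: float = 2.0
    motif_threshold: float = 8.0e-7
    motif_merge: int = 101
    entropy_base: float | None = None  # None = natural log
    effective_genome_length: int | None = None
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        positives = {
            "bin_size": self.bin_size,
            "max_fragment": self.max_fragment,
            "fdr": self.fdr,
            "merge_gap": self.merge_gap,
            "extension": self.extension,
            "motif_threshold": self.motif_threshold,
            "motif_merge": self.motif_merge,
        }
        for name, value in positives.items():
            if value <= 0 and not (name == "fdr" and value == 0):
                raise ValueError(f"{name} must be positive")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(**{k: v for k, v in raw.items()}, simulation=sim) if raw else cls(
            simulation=sim
        )
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["samples"] = list(self.simulation.samples)
        return d
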