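"""Simulation configuration.

A single :class:`SimulationConfig` drives the whole synthetic dataset: one
toy chromosome, ``n_genes`` non-overlapping multi-exon genes, a two-condition
RNA-seq experiment with planted fold-change genes and planted splicing-ratio
shifts, and an IP/input RIP experiment with planted enriched peaks.

The seed fully determines every downstream byte: genome sequence, gene
structures, planted signals, and all simulated reads.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclasses.dataclass
class SimulationConfig:
    seed: int = 1
    n_genes: int = 200
    genome_length: int = 2_000_000
    chrom: str = "chrS"

    # RNA-seq experiment: two conditions x n replicates
    n_replicates_per_condition: int = 3
    rnaseq_depth: int = 300_000          # expected fragments per library
    read_length: int = 100               # bp, single-record fragment representation

    # RIP experiment: IP + matched total-lysate input, per replicate
    n_rip_replicates: int = 2
    rip_depth: int = 100_000             # expected fragments per IP/input library
    rip_read_length: int = 50            # bp

    # Planted differential expression
    planted_deg_fraction: float = 0.15
    fold_change: float = 4.0             # condition B / condition A for "up" genes

    # Planted splicing shifts (ten event types, cycled)
    planted_as_fraction: float = 0.25
    ratio_shift: float = 0.4             # |ratio_B - ratio_A|, centred on 0.5

    # Planted binding peaks
    planted_peak_fraction: float = 0.3   # genes with an IP-only enriched peak
    planted_artifact_fraction: float = 0.1  # genes with a shared IP+input peak
    enrichment: float = 10.0             # fold concentration of IP reads in peaks
    peak_width: int = 100                # bp
    motif: str = "GCGCG"                 # embedded at motif-bearing peak centres
    motif_fraction: float = 0.5          # fraction of IP-only peaks carrying the motif

    coding_fraction: float = 0.8
    expression_sigma: float = 0.5        # lognormal sd of per-gene expression weights
    stranded: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # condition inclusion ratios for planted AS genes, centred on 0.5
    @property
    def ratio_a(self) -> float:
        return 0.5 - self.ratio_shift / 2.0

    @property
    def ratio_b(self) -> float:
        return 0.5 + self.ratio_shift / 2.0

    def validate(self) -> None:
        for name in (
            "planted_deg_fraction",
            "planted_as_fraction",
            "planted_peak_fraction",
            "planted_artifact_fraction",
            "motif_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 <= self.ratio_shift <= 1.0:
            raise ConfigError(f"ratio_shift={self.ratio_shift} must lie in [0, 1]")
        if not (0.0 <= self.ratio_a <= 1.0 and 0.0 <= self.ratio_b <= 1.0):
            raise ConfigError("ratio_shift pushes a condition ratio outside [0, 1]")
        if self.planted_peak_fraction + self.planted_artifact_fraction > 1.0:
            raise ConfigError("peak and artifact fractions together exceed 1")
        if self.fold_change <= 0:
            raise ConfigError("fold_change must be positive")
        if self.enrichment < 1.0:
            raise ConfigError("enrichment must be >= 1")
        if set(self.motif) - set("ACGT"):
            raise ConfigError("motif must be an ACGT string")
        for name in ("n_genes", "genome_length", "read_length", "rip_read_length",
                     "peak_width", "n_replicates_per_condition", "n_rip_replicates"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.rnaseq_depth < 0 or self.rip_depth < 0:
            raise ConfigError("library depths must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
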