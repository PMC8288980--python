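"""Run configuration shared by every pipeline stage.

All stage parameters live in one validated dataclass so that a YAML file plus
a seed fully determines a run. Every source of randomness draws from a named
substream derived from ``rng_seed``, which makes re-runs bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_rng"]


@dataclass
class RunConfig:
    """Parameters of the selection-scan and convergence pipeline.

    Parameters
    ----------
    top_fraction
        Fraction of genes called positively selected (PSG), default the
        top 1% of gene-level iFXD values.
    site_percentile
        Genome-wide percentile defining per-SNP outliers in the site-level
        convergence comparison (default 0.99, i.e. the 99th percentile).
    ortholog_top_fraction
        Per-species fraction defining "high iFXD" genes in the
        at-least-k-species count (default 0.05, i.e. 95% percentile rank).
    min_species_shared
        Minimum number of species a gene must be a PSG in to count as shared.
    window_bp, step_bp
        Sliding-window size and step in bp (defaults 50 kb / 25 kb).
    n_permutations
        Number of random draws for every permutation null (default 1000).
    ehh_cutoff
        EHH level at which haplotype-homozygosity integration stops.
    ehh_max_extend_bp
        Hard bound on the integration distance per side (bp); saturated
        regions that never cross the cutoff are truncated here and flagged.
    min_snps_per_gene
        Genes with fewer scored SNPs are excluded from gene ranking.
    flank_bp
        Flank added to gene bodies when assigning SNPs to genes (default 0:
        gene body only).
    rng_seed
        Master seed; per-stage streams are derived from it by name.
    """

    top_fraction: float = 0.01
    site_percentile: float = 0.99
    ortholog_top_fraction: float = 0.05
    min_species_shared: int = 2
    window_bp: int = 50_000
    step_bp: int = 25_000
    n_permutations: int = 1000
    ehh_cutoff: float = 0.05
    ehh_max_extend_bp: float = 500_000.0
    min_snps_per_gene: int = 3
    flank_bp: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("top_fraction", "site_percentile", "ortholog_top_fraction",
                     "ehh_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.window_bp >= self.step_bp > 0:
            raise ValueError("require window_bp >= step_bp > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_species_shared < 2:
            raise ValueError("min_species_shared must be >= 2")
        if self.min_snps_per_gene < 1:
            raise ValueError("min_snps_per_gene must be >= 1")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def rng(self, stage: str) -> np.random.Generator:
        """Named per-stage random stream derived from ``rng_seed``."""
        return stage_rng(self.rng_seed, stage)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named substream of a master seed.

    The stage name is hashed with CRC32 so the mapping is stable across
    sessions and platforms; distinct stages get statistically independent
    streams via ``SeedSequence``.
    """
    tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
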