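"""In-memory container for one species' phased two-population SNP panel.

A :class:`SitePanel` holds biallelic, phased SNPs for a highland and a lowland
population sample. Haplotypes are stored as ALT-allele indicator matrices
(rows = haplotypes, columns = sites). Ancestral polarity is carried per site:
where the ancestral allele (from an outgroup) matches REF, the derived allele
is ALT, and vice versa; sites whose ancestral allele is missing or matches
neither allele are retained but flagged unpolarized and excluded from
derived-allele-frequency statistics.

Positions are 1-based bp (VCF convention) and strictly increasing within each
chromosome; all interval arithmetic elsewhere is half-open 0-based, converted
only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SitePanel"]


@dataclass
class SitePanel:
    species: str
    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int, 1-based bp
    snp_id: np.ndarray         # (n_sites,) str
    ref: np.ndarray            # (n_sites,) str
    alt: np.ndarray            # (n_sites,) str
    polarized: np.ndarray      # (n_sites,) bool
    derived_is_alt: np.ndarray  # (n_sites,) bool; meaningful where polarized
    hap_high: np.ndarray       # (n_hap_high, n_sites) uint8, ALT dosage
    hap_low: np.ndarray        # (n_hap_low, n_sites) uint8
    samples_high: list[str]
    samples_low: list[str]
    gene_id: np.ndarray | None = None     # '' where intergenic
    func_class: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "snp_id", "ref", "alt", "polarized", "derived_is_alt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.hap_high.shape[1] != n or self.hap_low.shape[1] != n:
            raise ValueError("haplotype matrix width != number of sites")
        for chrom in pd.unique(self.chrom):
            p = self.pos[self.chrom == chrom]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_hap_high(self) -> int:
        return self.hap_high.shape[0]

    @property
    def n_hap_low(self) -> int:
        return self.hap_low.shape[0]

    def derived_matrix(self, which: str) -> np.ndarray:
        """Haplotypes recoded as derived-allele indicators (unpolarized sites
        are returned in ALT coding; callers must mask them)."""
        hap = self.hap_high if which == "high" else self.hap_low
        out = hap.copy()
        flip = self.polarized & ~self.derived_is_alt
        out[:, flip] = 1 - out[:, flip]
        return out

    def derived_freq(self, which: str) -> np.ndarray:
        """Per-site derived allele frequency; NaN at unpolarized sites."""
        daf = self.derived_matrix(which).mean(axis=0).astype(float)
        daf[~self.polarized] = np.nan
        return daf

    def alt_freq(self, which: str) -> np.ndarray:
        hap = self.hap_high if which == "high" else self.hap_low
        return hap.mean(axis=0)

    def swapped(self) -> "SitePanel":
        """Panel with population labels exchanged (for symmetry checks)."""
        return SitePanel(
            species=self.species, chrom=self.chrom, pos=self.pos,
            snp_id=self.snp_id, ref=self.ref, alt=self.alt,
            polarized=self.polarized, derived_is_alt=self.derived_is_alt,
            hap_high=self.hap_low, hap_low=self.hap_high,
            samples_high=self.samples_low, samples_low=self.samples_high,
            gene_id=self.gene_id, func_class=self.func_class,
            meta=dict(self.meta),
        )

    def annotate(self, annotation: pd.DataFrame) -> "SitePanel":
        """Attach gene assignment and functional class from an annotation
        table (columns snp_id, gene_id, class), matched on snp_id."""
        ann = annotation.set_index("snp_id")
        missing = [s for s in self.snp_id if s not in ann.index]
        if missing:
            raise ValueError(f"{len(missing)} panel SNPs missing from annotation "
                             f"(first: {missing[0]})")
        sub = ann.loc[self.snp_id]
        self.gene_id = sub["gene_id"].fillna("").to_numpy(dtype=object)
        self.func_class = sub["class"].to_numpy(dtype=object)
        return self
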