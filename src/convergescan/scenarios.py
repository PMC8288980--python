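"""Canonical synthetic study conditions.

These scenario factories freeze the simulation conditions used by the
calibration and recovery experiments (and by ``scripts/acceptance.py``), so
that every entry point exercises the same synthetic cohorts:

* ``neutral_pair`` — a neutral two-population panel (no sweep): 200 diploids
  per population, two 250 kb contigs with ~2500 SNPs each (~5k total),
  80 generations since the split, weak migration. Used for null calibration.
* ``sweep_genome`` — a one-species genome of eight 125 kb contigs (~10k SNPs
  in total over 1 Mb, 500 diploids per population) with a hard highland
  sweep (s = 0.1, run to near-fixation) at the center of one gene; ~400
  genes in total so the top-1% PSG call has room for the sweep's
  hitchhiking shoulder, as in a genome-scale scan.
* ``multispecies_genomes`` — six pseudo-species at reduced per-species size
  (100 diploids per population, six 60 kb contigs, ~600 genes) with hard
  sweeps planted in shared ortholog groups: one focal group swept in three
  species plus five groups swept in species pairs.

Sample sizes, rates and durations are chosen so that a sweep reaches
fixation at s = 0.1 while post-split drift stays mild enough for haplotype
statistics to retain contrast; docs/methods.md discusses the scaling.
"""

from __future__ import annotations

from .simulate import (MultiSpeciesData, SimulationConfig, SweepConfig,
                       make_multispecies)

__all__ = ["neutral_pair", "sweep_genome", "multispecies_genomes",
           "SWEEP_GENOME_SWEPT_GROUP", "MULTI_FOCAL_GROUP",
           "MULTI_SWEEP_PLAN"]

#: Ortholog-group index carrying the sweep in ``sweep_genome`` (region 3,
#: gene 25 of 50).
SWEEP_GENOME_SWEPT_GROUP = 3 * 50 + 25

#: Focal group for the six-species scenario: swept in species 0, 1, 2.
MULTI_FOCAL_GROUP = 1 * 100 + 50

#: group index -> species carrying a sweep there (six-species scenario).
MULTI_SWEEP_PLAN: dict[int, list[int]] = {
    MULTI_FOCAL_GROUP: [0, 1, 2],
    0 * 100 + 50: [0, 3],
    2 * 100 + 50: [1, 4],
    3 * 100 + 50: [2, 5],
    4 * 100 + 50: [3, 4],
    5 * 100 + 50: [4, 5],
}


def neutral_pair(seed: int, n_regions: int = 2) -> MultiSpeciesData:
    """Neutral two-population genome for null calibration."""
    base = SimulationConfig(
        n_dip_high=200, n_dip_low=200, L_bp=250_000, n_sites_target=2_500,
        n_generations_split=80, migration_rate=0.001, r=2e-5,
    )
    return make_multispecies(base, n_species=1, n_regions=n_regions,
                             n_genes_per_region=60, shared_sweep_groups={},
                             mean_gene_span=2000, seed=seed)


def sweep_genome(seed: int) -> MultiSpeciesData:
    """One species, 1 Mb over 8 contigs, hard sweep run to near-fixation."""
    base = SimulationConfig(
        n_dip_high=500, n_dip_low=500, L_bp=125_000, n_sites_target=1_250,
        n_generations_split=180, migration_rate=0.0002, r=2e-5,
        sweep=SweepConfig(s=0.1, min_final_daf=0.98,
                          max_extra_generations=300),
    )
    return make_multispecies(base, n_species=1, n_regions=8,
                             n_genes_per_region=50,
                             shared_sweep_groups={SWEEP_GENOME_SWEPT_GROUP: [0]},
                             mean_gene_span=1500, seed=seed)


def multispecies_genomes(seed: int) -> MultiSpeciesData:
    """Six pseudo-species with sweeps planted in shared ortholog groups."""
    # The six pseudo-species run at reduced size; a stronger sweep fixes
    # within the short split history so post-split drift stays mild (the
    # s = 0.1 detection-power question belongs to sweep_genome).
    base = SimulationConfig(
        n_dip_high=150, n_dip_low=150, L_bp=80_000, n_sites_target=2_000,
        n_generations_split=50, migration_rate=0.0002, r=1.5e-4,
        sweep=SweepConfig(s=0.5, min_final_daf=0.9,
                          max_extra_generations=200),
    )
    return make_multispecies(base, n_species=6, n_regions=6,
                             n_genes_per_region=100,
                             shared_sweep_groups=MULTI_SWEEP_PLAN,
                             mean_gene_span=700, seed=seed)
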