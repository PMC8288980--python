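"""Synthetic data with known ground truth for every pipeline input.

The sequence simulator is a forward-in-time Wright-Fisher model on a binary
haplotype lattice: an ancestral population at mutation-drift equilibrium is
split into a highland and a lowland population that exchange symmetric
migrants each generation, with per-generation mutation (infinite sites on an
integer bp grid) and single-crossover recombination. An optional hard sweep
gives the derived allele at one site genotype fitnesses 1 / 1+hs / 1+s in the
highland population only.

Ancestral standing variation is drawn directly from the neutral site-frequency
spectrum (P(i copies) proportional to 1/i) on an all-zero ancestral
background, instead of burning in for ~4N generations; founders therefore
start at linkage equilibrium, and all linkage disequilibrium in the final
panels is generated by the simulated post-split drift, migration,
recombination and hitchhiking. The ancestral state of every site is the zero
allele by construction, so outgroup polarization is exact (an optional
mislabeling rate corrupts the emitted AA field to probe ΔDAF robustness).

Beyond haplotype panels the module generates gene annotations, six
pseudo-species ortholog maps with sweeps planted in shared ortholog groups,
cross-species coordinate maps, interaction networks with a planted dense
module, gene sets, and quantitative trait tables with a genotype effect at
the swept SNP.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SitePanel

__all__ = [
    "SweepConfig", "SimulationConfig", "TruthRecord", "SweepLostError",
    "simulate_pair", "make_annotation", "make_multispecies", "make_network",
    "make_traits", "merge_panels", "neutral_drift_final_freqs",
    "MultiSpeciesData", "DEFAULT_CLASS_PROBS",
]


class SweepLostError(RuntimeError):
    """The selected allele was lost more often than the retry budget allows."""


@dataclass
class SweepConfig:
    on: bool = False
    s: float = 0.1          # selection coefficient of the derived homozygote
    h: float = 0.5          # dominance of the derived allele
    pos_bp: int = 0         # 1-based position of the selected site
    start_gen: int = 0      # post-split generation at which the mutation arises
    # Run-to-fixation support: if min_final_daf > 0, the simulation keeps
    # running past the nominal split time (up to max_extra_generations more)
    # until the highland derived frequency reaches the threshold, and errors
    # out instead of returning an unswept panel labeled as a sweep.
    min_final_daf: float = 0.0
    max_extra_generations: int = 300

    def __post_init__(self) -> None:
        if self.on and not 0.0 < self.s <= 1.0:
            raise ValueError("selection coefficient s must lie in (0, 1]")


@dataclass
class SimulationConfig:
    """Two-population Wright-Fisher scenario.

    Defaults emulate a recently split pair of domestic-mammal populations at
    desk scale: two samples of 100 diploids each, 100 generations since the
    split, weak symmetric migration, a 500 kb region with ~5000 segregating
    SNPs and a flat recombination map.
    """

    n_dip_high: int = 100
    n_dip_low: int = 100
    n_dip_anc: int | None = None          # default: n_dip_high + n_dip_low
    n_generations_split: int = 100
    migration_rate: float = 0.005         # per-generation migrant fraction
    mu: float = 1e-8                      # per-site per-generation
    # Per-adjacent-site-pair crossover probability. The post-split phase is
    # short, so background LD is inherited mainly from the coalescent
    # founders; r is kept small (~5% crossover probability per meiosis
    # across the region with ~10⁴ sites) so that a sweep lasting ~2·ln(2N)/s
    # generations drags a long, mostly intact haplotype, as a real sweep
    # does over the sub-Mb scales where haplotype tests operate.
    r: float = 5e-6
    L_bp: int = 500_000
    n_sites_target: int = 5_000
    sweep: SweepConfig = field(default_factory=SweepConfig)
    seed: int = 0
    aa_mislabel_rate: float = 0.0         # fraction of sites with wrong AA
    max_sweep_retries: int = 100
    sfs_inflation: float = 2.0            # oversampling so drift losses land near target
    # Founder model for ancestral standing variation. "coalescent" draws the
    # founder haplotypes from a neutral coalescent with recombination
    # (mutation-drift equilibrium, realistic background LD) — required for
    # meaningful haplotype statistics. "sfs" draws site frequencies from the
    # neutral SFS with carriers at linkage equilibrium (faster; fine for
    # frequency-based statistics only).
    founder: str = "coalescent"
    anc_ne: float = 10_000.0              # coalescent ancestral effective size
    anc_r_per_bp: float = 1e-8            # coalescent recombination rate

    def __post_init__(self) -> None:
        if isinstance(self.sweep, dict):
            # YAML 1.1 loaders parse a bare "on" key as boolean True
            self.sweep = SweepConfig(**{("on" if k is True else k): v
                                        for k, v in self.sweep.items()})
        if not 0.0 <= self.migration_rate < 0.5:
            raise ValueError("migration_rate must lie in [0, 0.5)")
        if self.sweep.on and not 1 <= self.sweep.pos_bp <= self.L_bp:
            raise ValueError("sweep.pos_bp must lie in [1, L_bp]")
        if self.n_sites_target >= self.L_bp:
            raise ValueError("n_sites_target must be < L_bp (infinite sites)")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside synthetic data."""

    swept_sites: dict = field(default_factory=dict)    # species -> snp_id
    swept_genes: dict = field(default_factory=dict)    # species -> [gene_id]
    swept_groups: list = field(default_factory=list)   # ortholog group ids
    module_members: list = field(default_factory=list)
    trait_beta: dict = field(default_factory=dict)     # trait name -> beta

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Wright-Fisher machinery


def _standing_variation(rng: np.random.Generator, n_hap: int, L_bp: int,
                        n_sites: int, exclude: set[int]) -> tuple[np.ndarray, np.ndarray]:
    """Positions and haplotype matrix of ancestral standing variation.

    Derived counts follow the neutral SFS P(i) ~ 1/i, i = 1..n_hap-1;
    carriers are assigned uniformly (linkage equilibrium)."""
    pool = rng.choice(L_bp, size=min(L_bp, n_sites + len(exclude)), replace=False) + 1
    positions = np.array(sorted(p for p in pool if p not in exclude)[:n_sites],
                         dtype=np.int64)
    n_sites = len(positions)
    i = np.arange(1, n_hap)
    w = 1.0 / i
    counts = rng.choice(i, size=n_sites, p=w / w.sum())
    # scatter counts[j] ones into random rows of column j (partial shuffle)
    H = np.zeros((n_hap, n_sites), dtype=np.uint8)
    idx = np.arange(n_hap)
    for j in range(n_sites):
        c = int(counts[j])
        pick = rng.permuted(idx)[:c] if c > n_hap // 2 else \
            rng.choice(n_hap, size=c, replace=False)
        H[pick, j] = 1
    return positions, H


def _coalescent_variation(rng: np.random.Generator, n_hap: int, L_bp: int,
                          n_sites: int, exclude: set[int], anc_ne: float,
                          anc_r_per_bp: float) -> tuple[np.ndarray, np.ndarray]:
    """Founder haplotypes from a neutral coalescent with recombination.

    The mutation rate is solved from Watterson's formula so the expected
    segregating-site count hits ``n_sites``; the realized count is Poisson
    around it. Sites are biallelic, derived allele coded 1 (the coalescent
    ancestral state), positions on the integer bp grid."""
    import msprime

    a_n = float(np.sum(1.0 / np.arange(1, n_hap)))
    mu_anc = n_sites / (4.0 * anc_ne * L_bp * a_n)
    seed1, seed2 = (int(s) for s in rng.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples=n_hap // 2, ploidy=2, population_size=anc_ne,
        sequence_length=L_bp, recombination_rate=anc_r_per_bp,
        random_seed=seed1)
    ts = msprime.sim_mutations(ts, rate=mu_anc, random_seed=seed2,
                               model=msprime.BinaryMutationModel())
    G = ts.genotype_matrix()          # (sites, n_hap), 0/1 under binary model
    positions = ts.tables.sites.position.astype(np.int64) + 1  # to 1-based
    # biallelic, inside the grid, not at excluded positions, unique positions
    keep = (G.max(axis=1) <= 1) & (positions >= 1) & (positions <= L_bp)
    keep &= ~np.isin(positions, list(exclude)) if exclude else True
    uniq = np.concatenate([[True], np.diff(positions) > 0])
    keep &= uniq
    seg = (G.sum(axis=1) > 0) & (G.sum(axis=1) < n_hap)
    keep &= seg
    return positions[keep], np.ascontiguousarray(G[keep].T.astype(np.uint8))


def _gametes(parents_hap: np.ndarray, parent_idx: np.ndarray, r_total: float,
             pos_arr: np.ndarray, sorted_pos: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per entry of ``parent_idx`` (diploid row pairs 2i, 2i+1).

    Single crossover with probability ``r_total``; the breakpoint falls in a
    uniformly chosen gap between *physically* adjacent sites (columns are
    stored in append order, so the comparison is on bp positions, not on
    column indices)."""
    n_gam = len(parent_idx)
    S = parents_hap.shape[1]
    start = rng.integers(0, 2, size=n_gam)
    rows_a = 2 * parent_idx + start
    rows_b = 2 * parent_idx + 1 - start
    out = parents_hap[rows_a]
    if S > 1 and r_total > 0:
        rec = np.nonzero(rng.random(n_gam) < r_total)[0]
        if len(rec):
            gap = rng.integers(1, S, size=len(rec))
            cutpos = sorted_pos[gap]  # sites with pos < cutpos from hap a
            out = out.copy()
            out[rec] = np.where(pos_arr[None, :] < cutpos[:, None],
                                parents_hap[rows_a[rec]],
                                parents_hap[rows_b[rec]])
    return np.ascontiguousarray(out)


def _choose_parents(n_children: int, weights: np.ndarray | None, n_parents: int,
                    rng: np.random.Generator) -> np.ndarray:
    if weights is None:
        return rng.integers(0, n_parents, size=n_children)
    p = weights / weights.sum()
    return rng.choice(n_parents, size=n_children, p=p)


def _next_generation(H_self: np.ndarray, H_other: np.ndarray,
                     w_self: np.ndarray | None, w_other: np.ndarray | None,
                     n_dip: int, migration_rate: float, r_total: float,
                     rng: np.random.Generator,
                     pos_arr: np.ndarray | None = None,
                     sorted_pos: np.ndarray | None = None) -> np.ndarray:
    """Children of one population: Wright-Fisher with selection weights,
    symmetric migration (a migrant child's parents come from the other
    population) and single-crossover recombination."""
    if pos_arr is None:
        pos_arr = np.arange(H_self.shape[1], dtype=np.int64)
        sorted_pos = pos_arr
    n_self = H_self.shape[0] // 2
    n_other = H_other.shape[0] // 2
    migrant = rng.random(n_dip) < migration_rate
    n_mig = int(migrant.sum())
    parent_idx = np.empty(2 * n_dip, dtype=np.int64)
    source_other = np.repeat(migrant, 2)
    parent_idx[~source_other] = _choose_parents(
        int((~source_other).sum()), w_self, n_self, rng)
    if n_mig:
        parent_idx[source_other] = _choose_parents(2 * n_mig, w_other, n_other, rng)
    children = np.empty((2 * n_dip, H_self.shape[1]), dtype=np.uint8)
    if (~source_other).any():
        children[~source_other] = _gametes(
            H_self, parent_idx[~source_other], r_total, pos_arr, sorted_pos, rng)
    if n_mig:
        children[source_other] = _gametes(
            H_other, parent_idx[source_other], r_total, pos_arr, sorted_pos, rng)
    return children


def _sweep_weights(H: np.ndarray, col: int, s: float, h: float) -> np.ndarray:
    g = H[0::2, col].astype(np.int64) + H[1::2, col]
    return 1.0 + np.where(g == 2, s, 0.0) + np.where(g == 1, h * s, 0.0)


def simulate_pair(config: SimulationConfig) -> tuple[SitePanel, TruthRecord]:
    """Simulate one species' highland/lowland panel.

    Returns the phased :class:`SitePanel` (pooled-polymorphic sites only) and
    a :class:`TruthRecord` naming the swept site, if any. If the sweep allele
    is lost it is re-seeded as a fresh mutation, up to
    ``config.max_sweep_retries`` times; exhausting the budget raises
    :class:`SweepLostError` rather than returning a mislabeled neutral panel.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x5EED]))
    n_anc = config.n_dip_anc or (config.n_dip_high + config.n_dip_low)
    sweep = config.sweep
    exclude = {sweep.pos_bp} if sweep.on else set()
    n_init = int(round(config.n_sites_target * config.sfs_inflation))
    if config.founder == "coalescent":
        positions, H_anc = _coalescent_variation(
            rng, 2 * n_anc, config.L_bp, n_init, exclude,
            config.anc_ne, config.anc_r_per_bp)
    elif config.founder == "sfs":
        positions, H_anc = _standing_variation(rng, 2 * n_anc, config.L_bp,
                                               n_init, exclude)
    else:
        raise ValueError(f"unknown founder model {config.founder!r}")
    perm = rng.permutation(2 * n_anc)
    H_hi = H_anc[perm[: 2 * config.n_dip_high]].copy()
    H_lo = H_anc[perm[2 * config.n_dip_high:
                      2 * (config.n_dip_high + config.n_dip_low)]].copy()
    del H_anc
    positions = list(positions)
    occupied = set(positions)
    sweep_col = -1
    retries = 0

    def inject_sweep() -> int:
        nonlocal H_hi, H_lo, positions, sweep_col
        if sweep_col < 0:
            # de novo mutation at pos_bp: append a fresh all-zero column
            H_hi = np.hstack([H_hi, np.zeros((H_hi.shape[0], 1), np.uint8)])
            H_lo = np.hstack([H_lo, np.zeros((H_lo.shape[0], 1), np.uint8)])
            positions.append(sweep.pos_bp)
            occupied.add(sweep.pos_bp)
            sweep_col = H_hi.shape[1] - 1
        H_hi[rng.integers(0, H_hi.shape[0]), sweep_col] = 1
        return sweep_col

    gen = 0
    while True:
        if gen >= config.n_generations_split:
            if not (sweep.on and sweep.min_final_daf > 0):
                break
            freq = H_hi[:, sweep_col].mean() if sweep_col >= 0 else 0.0
            if freq >= sweep.min_final_daf:
                break
            if gen >= config.n_generations_split + sweep.max_extra_generations:
                raise SweepLostError(
                    f"highland derived frequency {freq:.3f} below "
                    f"min_final_daf={sweep.min_final_daf} after "
                    f"{gen} generations")
        if sweep.on and gen >= sweep.start_gen:
            if sweep_col < 0:
                inject_sweep()
            elif H_hi[:, sweep_col].sum() == 0:
                retries += 1
                if retries > config.max_sweep_retries:
                    raise SweepLostError(
                        f"sweep allele lost {retries} times (budget "
                        f"{config.max_sweep_retries})")
                inject_sweep()
        S = H_hi.shape[1]
        r_total = min(config.r * max(S - 1, 0), 1.0)
        pos_np = np.asarray(positions, dtype=np.int64)
        sorted_pos = np.sort(pos_np)
        w_hi = (_sweep_weights(H_hi, sweep_col, sweep.s, sweep.h)
                if sweep.on and sweep_col >= 0 else None)
        new_hi = _next_generation(H_hi, H_lo, w_hi, None, config.n_dip_high,
                                  config.migration_rate, r_total, rng,
                                  pos_np, sorted_pos)
        new_lo = _next_generation(H_lo, H_hi, None, w_hi, config.n_dip_low,
                                  config.migration_rate, r_total, rng,
                                  pos_np, sorted_pos)
        H_hi, H_lo = new_hi, new_lo
        # infinite-sites mutation on unoccupied positions (batched per pop)
        lam = config.mu * config.L_bp
        new_cols: list[tuple[str, int]] = []  # (pop, carrier row)
        for pop, n_rows in (("high", H_hi.shape[0]), ("low", H_lo.shape[0])):
            for _ in range(rng.poisson(lam * n_rows)):
                while True:
                    p = int(rng.integers(1, config.L_bp + 1))
                    if p not in occupied:
                        break
                occupied.add(p)
                positions.append(p)
                new_cols.append((pop, int(rng.integers(0, n_rows))))
        if new_cols:
            k = len(new_cols)
            blk_hi = np.zeros((H_hi.shape[0], k), np.uint8)
            blk_lo = np.zeros((H_lo.shape[0], k), np.uint8)
            for c, (pop, carrier) in enumerate(new_cols):
                (blk_hi if pop == "high" else blk_lo)[carrier, c] = 1
            H_hi = np.hstack([H_hi, blk_hi])
            H_lo = np.hstack([H_lo, blk_lo])
        # periodically drop columns that can never segregate again
        if gen % 16 == 15:
            pooled = H_hi.sum(axis=0).astype(np.int64) + H_lo.sum(axis=0)
            n_tot = H_hi.shape[0] + H_lo.shape[0]
            live = (pooled > 0) & (pooled < n_tot)
            if sweep_col >= 0:
                live[sweep_col] = True
            if not live.all():
                H_hi = np.ascontiguousarray(H_hi[:, live])
                H_lo = np.ascontiguousarray(H_lo[:, live])
                positions = [p for p, ok in zip(positions, live) if ok]
                if sweep_col >= 0:
                    sweep_col = int(np.nonzero(live)[0].searchsorted(sweep_col))
        gen += 1

    if sweep.on and (sweep_col < 0 or H_hi[:, sweep_col].sum() == 0):
        raise SweepLostError("sweep allele absent at sampling time")

    pos_arr = np.asarray(positions, dtype=np.int64)
    order = np.argsort(pos_arr)
    pos_arr = pos_arr[order]
    H_hi = H_hi[:, order]
    H_lo = H_lo[:, order]
    pooled_count = H_hi.sum(axis=0).astype(np.int64) + H_lo.sum(axis=0)
    n_hap_total = H_hi.shape[0] + H_lo.shape[0]
    keep = (pooled_count > 0) & (pooled_count < n_hap_total)
    if sweep.on:
        sweep_keep = pos_arr == sweep.pos_bp
        if not keep[sweep_keep].all():
            raise SweepLostError("sweep site monomorphic in the pooled sample")
    pos_arr = pos_arr[keep]
    H_hi = np.ascontiguousarray(H_hi[:, keep])
    H_lo = np.ascontiguousarray(H_lo[:, keep])
    n_sites = len(pos_arr)

    chrom_name = "1"
    snp_id = np.array([f"{chrom_name}_{p}" for p in pos_arr], dtype=object)
    derived_is_alt = np.ones(n_sites, dtype=bool)
    if config.aa_mislabel_rate > 0:
        flip = rng.random(n_sites) < config.aa_mislabel_rate
        derived_is_alt[flip] = False
    panel = SitePanel(
        species="species",
        chrom=np.full(n_sites, chrom_name, dtype=object),
        pos=pos_arr,
        snp_id=snp_id,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        polarized=np.ones(n_sites, dtype=bool),
        derived_is_alt=derived_is_alt,
        hap_high=H_hi,
        hap_low=H_lo,
        samples_high=[f"hi{i:04d}" for i in range(config.n_dip_high)],
        samples_low=[f"lo{i:04d}" for i in range(config.n_dip_low)],
        meta={"config": dataclasses.asdict(config), "sweep_retries": retries},
    )
    truth = TruthRecord()
    if sweep.on:
        truth.swept_sites["species"] = f"{chrom_name}_{sweep.pos_bp}"
    return panel, truth


def neutral_drift_final_freqs(n_dip: int, p0: float, n_generations: int,
                              n_replicates: int, seed: int = 0) -> np.ndarray:
    """Final allele frequencies of a single neutral site started at ``p0``,
    run through the same per-generation reproduction machinery (one site,
    one population, no migration). Used to validate drift behavior against
    the closed-form Wright-Fisher variance p(1-p)(1-(1-1/2N)^t)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    n_hap = 2 * n_dip
    n_ones = int(round(p0 * n_hap))
    for rep in range(n_replicates):
        H = np.zeros((n_hap, 1), dtype=np.uint8)
        H[rng.permutation(n_hap)[:n_ones], 0] = 1
        for _ in range(n_generations):
            H = _next_generation(H, H, None, None, n_dip, 0.0, 0.0, rng)
        out[rep] = H[:, 0].mean()
    return out


# ---------------------------------------------------------------------------
# Annotation

#: Default functional-class mix for genic SNPs.
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "intronic": 0.55, "upstream": 0.08, "downstream": 0.08,
    "utr5": 0.02, "utr3": 0.04, "synonymous": 0.10,
    "nonsynonymous": 0.12, "splicing": 0.01,
}


def _place_genes(L_bp: int, n_genes: int, rng: np.random.Generator,
                 mean_gene_span: int) -> pd.DataFrame:
    """Non-overlapping gene intervals (1-based inclusive) packed into L_bp."""
    if n_genes == 0:
        return pd.DataFrame(columns=["gene_id", "start", "end"])
    spans = np.maximum(
        (mean_gene_span * rng.uniform(0.5, 1.5, size=n_genes)).astype(np.int64), 50)
    total = int(spans.sum())
    if total > L_bp:
        raise ValueError(f"cannot pack {n_genes} genes of mean span "
                         f"{mean_gene_span} into {L_bp} bp")
    gaps = rng.multinomial(L_bp - total, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(spans[:-1])]) + 1
    return pd.DataFrame({
        "gene_id": [f"G{i:05d}" for i in range(n_genes)],
        "start": starts,
        "end": starts + spans - 1,
    })


def make_annotation(panel: SitePanel, n_genes: int, seed: int,
                    mean_gene_span: int = 4000,
                    class_probs: dict[str, float] | None = None,
                    gene_prefix: str = "G") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene intervals plus a per-SNP annotation table for a one-chromosome
    panel. Genic SNPs draw a functional class from ``class_probs``; SNPs
    outside genes are intergenic. Returns (annotation, genes); the panel is
    annotated in place."""
    if len(pd.unique(panel.chrom)) != 1:
        raise ValueError("make_annotation expects a single-chromosome panel")
    chrom = panel.chrom[0]
    L_bp = int(panel.meta.get("config", {}).get("L_bp", panel.pos.max()))
    rng = np.random.default_rng(seed)
    genes = _place_genes(L_bp, n_genes, rng, mean_gene_span)
    genes["gene_id"] = [g.replace("G", gene_prefix, 1) for g in genes["gene_id"]]
    genes.insert(1, "chrom", chrom)
    probs = dict(class_probs or DEFAULT_CLASS_PROBS)
    names = sorted(probs)
    pvec = np.array([probs[k] for k in names])
    pvec = pvec / pvec.sum()

    gene_id = np.full(panel.n_sites, "", dtype=object)
    if n_genes:
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        idx = np.searchsorted(starts, panel.pos, side="right") - 1
        inside = (idx >= 0) & (panel.pos <= ends[np.clip(idx, 0, None)])
        gene_id[inside] = genes["gene_id"].to_numpy(dtype=object)[idx[inside]]
    func = np.full(panel.n_sites, "intergenic", dtype=object)
    genic = gene_id != ""
    func[genic] = rng.choice(names, size=int(genic.sum()), p=pvec)
    ann = pd.DataFrame({
        "snp_id": panel.snp_id, "chrom": panel.chrom, "pos": panel.pos,
        "gene_id": gene_id, "class": func,
    })
    panel.gene_id = gene_id
    panel.func_class = func
    return ann, genes


def merge_panels(panels: list[SitePanel]) -> SitePanel:
    """Concatenate single-chromosome panels (same samples) into one panel
    with multiple contigs."""
    first = panels[0]
    for p in panels[1:]:
        if p.n_hap_high != first.n_hap_high or p.n_hap_low != first.n_hap_low:
            raise ValueError("panels must have identical sample sizes")
    cat = lambda attr: np.concatenate([getattr(p, attr) for p in panels])
    return SitePanel(
        species=first.species,
        chrom=cat("chrom"), pos=cat("pos"), snp_id=cat("snp_id"),
        ref=cat("ref"), alt=cat("alt"),
        polarized=cat("polarized"), derived_is_alt=cat("derived_is_alt"),
        hap_high=np.hstack([p.hap_high for p in panels]),
        hap_low=np.hstack([p.hap_low for p in panels]),
        samples_high=first.samples_high, samples_low=first.samples_low,
        gene_id=(cat("gene_id") if first.gene_id is not None else None),
        func_class=(cat("func_class") if first.func_class is not None else None),
        meta={"merged": len(panels), **first.meta},
    )


# ---------------------------------------------------------------------------
# Multi-species scaffolding


@dataclass
class MultiSpeciesData:
    panels: dict            # species -> SitePanel (multi-contig)
    annotations: dict       # species -> annotation DataFrame
    orthologs: pd.DataFrame
    coord_map: pd.DataFrame
    truth: TruthRecord


def make_multispecies(
    base_config: SimulationConfig,
    n_species: int = 6,
    n_regions: int = 4,
    n_genes_per_region: int = 50,
    shared_sweep_groups: dict[int, list[int]] | None = None,
    coord_map_fraction: float = 0.5,
    mean_gene_span: int = 1500,
    seed: int = 0,
) -> MultiSpeciesData:
    """Six pseudo-species sharing a one-to-one ortholog universe.

    Each species consists of ``n_regions`` independently simulated contigs
    with ``n_genes_per_region`` genes each; gene ``g`` of every species
    belongs to ortholog group ``OG{g:05d}``. ``shared_sweep_groups`` maps an
    ortholog-group index to the species (indices) in which a hard sweep is
    planted at the center of that group's gene — at most one swept group per
    region, since each region carries a single sweep. The coordinate map
    links site ranks across species to a common reference frame, each site
    independently mapped with probability ``coord_map_fraction``.
    """
    shared_sweep_groups = shared_sweep_groups or {}
    n_genes_total = n_regions * n_genes_per_region
    regions_used: dict[int, int] = {}
    for g in shared_sweep_groups:
        if not 0 <= g < n_genes_total:
            raise ValueError(f"ortholog group index {g} outside universe")
        region = g // n_genes_per_region
        if region in regions_used:
            raise ValueError("at most one swept ortholog group per region")
        regions_used[region] = g
    master = np.random.SeedSequence(seed)
    species_seeds = master.spawn(n_species)

    panels: dict[str, SitePanel] = {}
    annotations: dict[str, pd.DataFrame] = {}
    orth_rows = []
    coord_rows = []
    truth = TruthRecord(swept_groups=[f"OG{g:05d}" for g in
                                      sorted(shared_sweep_groups)])
    map_rng = np.random.default_rng(master.spawn(1)[0])

    for s in range(n_species):
        sp = f"sp{s}"
        sub = species_seeds[s].generate_state(2 * n_regions) % (2**31 - 1)
        region_panels = []
        ann_frames = []
        swept_genes: list[str] = []
        for reg in range(n_regions):
            gene_rng = np.random.default_rng(int(sub[2 * reg]))
            genes = _place_genes(base_config.L_bp, n_genes_per_region,
                                 gene_rng, mean_gene_span)
            cfg = dataclasses.replace(
                base_config, seed=int(sub[2 * reg + 1]),
                sweep=dataclasses.replace(base_config.sweep, on=False))
            group_here = regions_used.get(reg)
            if group_here is not None and s in shared_sweep_groups[group_here]:
                local = group_here % n_genes_per_region
                center = int((genes["start"].iloc[local] +
                              genes["end"].iloc[local]) // 2)
                cfg = dataclasses.replace(
                    cfg, sweep=dataclasses.replace(
                        base_config.sweep, on=True, pos_bp=center))
            # a sweep occasionally fails to reach its fixation target inside
            # the generation budget; re-run the region on a perturbed seed
            # (the emitted panel always carries a genuine sweep)
            for attempt in range(8):
                try:
                    panel, _ = simulate_pair(cfg)
                    break
                except SweepLostError:
                    cfg = dataclasses.replace(
                        cfg, seed=(cfg.seed + 7919 * (attempt + 1)) % (2**31 - 1))
            else:
                raise SweepLostError(
                    f"region {reg} of species {s}: sweep failed in 8 attempts")
            chrom = f"chr{reg + 1}"
            panel.chrom = np.full(panel.n_sites, chrom, dtype=object)
            panel.snp_id = np.array([f"{sp}_{chrom}_{p}" for p in panel.pos],
                                    dtype=object)
            # classify sites against this region's genes
            genes_named = genes.copy()
            genes_named["gene_id"] = [
                f"{sp}_g{reg * n_genes_per_region + i:05d}"
                for i in range(n_genes_per_region)]
            gid = np.full(panel.n_sites, "", dtype=object)
            starts = genes_named["start"].to_numpy()
            ends = genes_named["end"].to_numpy()
            idx = np.searchsorted(starts, panel.pos, side="right") - 1
            inside = (idx >= 0) & (panel.pos <= ends[np.clip(idx, 0, None)])
            gid[inside] = genes_named["gene_id"].to_numpy(dtype=object)[idx[inside]]
            names = sorted(DEFAULT_CLASS_PROBS)
            pvec = np.array([DEFAULT_CLASS_PROBS[k] for k in names])
            func = np.full(panel.n_sites, "intergenic", dtype=object)
            genic = gid != ""
            func[genic] = gene_rng.choice(names, size=int(genic.sum()),
                                          p=pvec / pvec.sum())
            panel.gene_id = gid
            panel.func_class = func
            ann_frames.append(pd.DataFrame({
                "snp_id": panel.snp_id, "chrom": panel.chrom, "pos": panel.pos,
                "gene_id": gid, "class": func}))
            if cfg.sweep.on:
                truth.swept_sites.setdefault(sp, []).append(
                    f"{sp}_{chrom}_{cfg.sweep.pos_bp}")
                swept_genes.append(
                    f"{sp}_g{regions_used[reg]:05d}")
            region_panels.append(panel)
        merged = merge_panels(region_panels)
        merged.species = sp
        panels[sp] = merged
        annotations[sp] = pd.concat(ann_frames, ignore_index=True)
        truth.swept_genes[sp] = swept_genes
        orth_rows.extend(
            {"species": sp, "gene_id": f"{sp}_g{g:05d}",
             "ortholog_group": f"OG{g:05d}"}
            for g in range(n_genes_total))
        # coordinate map: site rank r of region reg maps to a shared frame
        for reg in range(n_regions):
            chrom = f"chr{reg + 1}"
            mask = merged.chrom == chrom
            pos_here = merged.pos[mask]
            mapped = map_rng.random(len(pos_here)) < coord_map_fraction
            for rank in np.nonzero(mapped)[0]:
                coord_rows.append({
                    "species": sp, "chrom": chrom, "pos": int(pos_here[rank]),
                    "ref_chrom": "ref", "ref_pos": reg * 10_000_000 + int(rank)})

    return MultiSpeciesData(
        panels=panels,
        annotations=annotations,
        orthologs=pd.DataFrame(orth_rows),
        coord_map=pd.DataFrame(coord_rows,
                               columns=["species", "chrom", "pos",
                                        "ref_chrom", "ref_pos"]),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Network, gene sets, traits


def make_network(groups: list[str], planted_module: list[str],
                 background_edge_prob: float, module_edge_prob: float,
                 seed: int = 0) -> pd.DataFrame:
    """Erdos-Renyi background network over ortholog groups plus a denser
    planted module; undirected, deduplicated, no self-loops."""
    missing = set(planted_module) - set(groups)
    if missing:
        raise ValueError(f"module members outside universe: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    groups = list(groups)
    n = len(groups)
    ia, ib = np.triu_indices(n, k=1)
    in_module = np.isin(groups, list(planted_module))
    pair_in_module = in_module[ia] & in_module[ib]
    p = np.where(pair_in_module, module_edge_prob, background_edge_prob)
    keep = rng.random(len(ia)) < p
    garr = np.array(groups, dtype=object)
    return pd.DataFrame({"gene_a": garr[ia[keep]], "gene_b": garr[ib[keep]]})


def make_traits(panel: SitePanel, focal_site: str, beta: float,
                sd_noise: float, n_traits: int = 21, seed: int = 0,
                intercept: float = 100.0) -> tuple[pd.DataFrame, TruthRecord]:
    """Quantitative trait table: trait_1 carries an additive genotype effect
    ``beta`` per derived allele at ``focal_site`` (a negative beta emulates a
    protective lower-hemoglobin association); remaining traits are pure
    noise. Individuals from both populations are emitted with their
    elevation class."""
    j = np.nonzero(panel.snp_id == focal_site)[0]
    if len(j) != 1:
        raise ValueError(f"focal site {focal_site!r} not found in panel")
    j = int(j[0])
    if not panel.polarized[j]:
        raise ValueError("focal site must be polarized")
    rng = np.random.default_rng(seed)
    rows = []
    for which, samples, elev in (("high", panel.samples_high, "highland"),
                                 ("low", panel.samples_low, "lowland")):
        D = panel.derived_matrix(which)[:, j]
        g = D[0::2].astype(int) + D[1::2]
        for name, gt in zip(samples, g):
            rows.append({"individual": name, "genotype": int(gt),
                         "elevation_class": elev})
    df = pd.DataFrame(rows)
    n = len(df)
    g = df["genotype"].to_numpy()
    for t in range(1, n_traits + 1):
        noise = rng.normal(0.0, sd_noise, size=n) if sd_noise > 0 else 0.0
        effect = beta * g if t == 1 else 0.0
        df[f"trait_{t}"] = intercept + effect + noise
    truth = TruthRecord(trait_beta={f"trait_{t}": (beta if t == 1 else 0.0)
                                    for t in range(1, n_traits + 1)})
    return df, truth
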