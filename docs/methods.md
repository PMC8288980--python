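# Methods

## Scope

`convergescan` implements a multi-species selection-scan and convergence
analysis for domestic mammals adapted to high altitude: per-SNP
differentiation statistics between a highland and a lowland population
(F_ST, XP-EHH, ΔDAF), a composite rank-based score (iFXD), gene- and
window-level outlier calling, cross-species convergence tests at the site
and gene level, interaction-network and gene-set enrichment, and a
genotype–trait association stage. A forward-in-time simulator generates
every input with known ground truth, so each stage can be validated by
parameter recovery and null calibration rather than by re-analyzing the
original cohorts.

## Per-SNP statistics

**F_ST.** The Weir–Cockerham (1984) two-population single-SNP estimator
θ̂ = a/(a+b+c), applied to haplotype counts (for haploid data the
within-individual component c vanishes). Negative estimates have no
biological interpretation and are set to 0. Sites monomorphic in the pooled
sample are flagged and excluded from all ranking.

**ΔDAF.** Derived allele frequency (highland) − derived allele frequency
(lowland). Polarization comes from the ancestral allele carried in the VCF
INFO/AA field (outgroup-derived); sites whose AA is missing or matches
neither allele are retained but excluded from ΔDAF ranking only.

**XP-EHH.** For a core SNP, EHH(x) is the probability that two random
haplotypes from a population are identical at every site from the core out
to distance x (full population sample, not allele-partitioned — the
cross-population construction). iHH is the trapezoidal integral of EHH over
physical distance, both directions summed. The integration limit is set
where the *pooled* two-population EHH first falls below the cutoff
(default 0.05, linearly interpolated), so both populations are integrated
over identical intervals and the log-ratio

    XP-EHH = ln(iHH_highland / iHH_lowland)

is not biased by unequal truncation. Distances are physical bp: no genetic
map is used. Raw scores are standardized genome-wide to mean 0, sd 1 over
all scored SNPs; positive values mean longer highland haplotypes.

Two numerical guards matter in practice. First, around a fixed sweep the
swept population contributes a constant fraction of identical pairs, so
pooled EHH can stay above the cutoff indefinitely; integration is therefore
also capped at `ehh_max_extend_bp` per side (default 500 kb, in the spirit
of the max-extension options of standard haplotype-scan tools) and such
sites carry an `edge_truncated` flag, as do sites whose walk reaches a
contig end. Second, repeated distances are merged before integration so
zero-length trapezoid segments cannot occur. The production scan is an
incremental partition-refinement walk (only the minor-allele carriers of
each site are touched per step, pair counts are updated by difference); it
is checked against a direct per-site reference implementation and against
exhaustive pair-counting oracles in the test suite.

## Composite score and outlier calling

Each statistic is converted to a selection probability Ps as its one-sided
empirical mid-rank probability genome-wide, Ps = (r − 0.5)/n with r the
ascending mid-rank. This choice reproduces the outlier logic of empirical
top-percentile scans, makes no parametric assumption, handles ties, and
keeps Ps strictly inside (0, 1) so the odds are finite. Per SNP,

    iFXD = ∏ᵢ Psᵢ / (1 − Psᵢ)

over the methods available at the SNP: a SNP missing one method (an
unpolarized site, or a failed XP-EHH) contributes the product over the
remaining methods and records its method count, rather than being dropped —
dropping incomplete SNPs entirely would bias against low-recombination and
unpolarizable regions.

Gene scores are arithmetic means of SNP iFXD over SNPs in the gene body
(a configurable flank is off by default; the source analysis does not state
whether flanking SNPs entered the averages). Genes with fewer than
`min_snps_per_gene` scored SNPs (default 3, configurable down to 1) are
excluded from ranking. The top `top_fraction` (default 1%) of genes by mean
iFXD are called positively selected (PSGs); boundary ties break
deterministically by (higher iFXD, more SNPs, lexicographic id). Sliding
windows (50 kb window, 25 kb step, half-open 0-based grid anchored at 0)
report mean SNP iFXD per window.

## Convergence across species

*Site level.* A SNP is an outlier for a statistic if it exceeds that
species' genome-wide 99th percentile. For a species pair, a convergent site
is a coordinate-mapped site pair that is an outlier in both species for at
least one statistic; per-statistic counts are reported alongside. The
coordinate map is consumed as input (a stand-in for a reference-genome
liftover).

*Gene level.* The shared-PSG count is the number of one-to-one ortholog
groups that are PSGs in at least `min_species` (default 2) species. Its
null distribution is built by drawing, per species, a uniform random gene
set of the observed PSG size from that species' scored-gene universe
(default 1000 draws); p-values use the add-one estimator so they are never
zero. The closed-form null mean (Poisson-binomial tail over per-species
inclusion probabilities) is used as an independent check. The CE score of
a group present in all species is the product of per-species gene-level
odds, CE = ∏ᵢ Psᵢ/(1 − Psᵢ); groups missing from any species are excluded,
not imputed. A companion count reports groups in the per-species top 5%
(Ps > 0.95) in ≥ 3 species, with its own permutation null.

The highland-vs-lowland shared-count contrast is reported as a 1-df
goodness-of-fit chi-square against equal expectation; the report carries an
explicit caveat that other contingency constructions of the same two counts
give different statistics.

## Network and gene-set enrichment

Interaction ratios follow the published convention literally: within a set
of N genes R = I/(N·(N−1)) with I counting undirected deduplicated edges
once — the complete graph thus attains R = 0.5 — and between two sets
R = I/(N₁·N₂). Observed ratios are compared with means over random
same-size sets drawn uniformly from the node universe (not degree-matched;
a degree-matched variant exists but is off by default to mirror the stated
procedure). Under an Erdős–Rényi(p) network the expected within-ratio is
p/2 under this denominator, which the tests verify.

Gene-set scans compare the per-SNP statistics of set SNPs against all other
genic SNPs and against size-matched random gene sets (median p over draws
reported) by Mann–Whitney U tests. Because SNP scores are correlated within
genes and linkage blocks, the raw rank-sum p-values treat far fewer
effectively independent observations than they claim and are
anticonservative; the scan therefore also reports an empirical calibrated
p — the add-one rank of the observed |z| among the |z| of the random
same-size sets — which is the quantity whose null distribution is uniform.
The tests are — exact by enumeration when
n₁·n₂ ≤ 200 and tie-free, otherwise the normal approximation with tie and
continuity corrections. Functional-class stratification compares
non-synonymous SNPs with every other annotation class; a candidate table
lists non-synonymous SNPs with F_ST > 0.5 inside PSGs together with a
highland-DAF comparison.

## Trait association

Genotype at the focal SNP is a categorical factor (derived-allele count
0/1/2) in a one-way ANOVA F test, per elevation stratum, matching a design
in which association is evaluated among individuals at the same altitude. A
genotype class with fewer than two individuals is merged with the minor
homozygote class (logged). P-values are BH-FDR corrected across traits
within each stratum. The direction of effect is the sign of (mean in
derived homozygotes − mean in ancestral homozygotes), so statements like
"the derived allele is associated with lower hemoglobin" can be read
directly; an additive slope is reported as a secondary column.

## The simulator

A forward Wright–Fisher model on a binary haplotype lattice: an ancestral
population is split into highland and lowland populations of fixed diploid
size that exchange symmetric migrants each generation, with per-generation
infinite-sites mutation on an integer bp grid and single-crossover
recombination whose breakpoint falls in a uniformly chosen gap between
physically adjacent sites. A hard sweep gives the derived allele at one
site genotype fitnesses 1/1+hs/1+s in the highland population only; a lost
sweep allele is re-seeded as a fresh mutation up to a bounded retry budget,
and an optional run-to-fixation mode extends the run (bounded) until a
target highland frequency is reached — in both cases failure raises an
error rather than mislabeling a neutral panel as a sweep.

Ancestral standing variation is drawn from a neutral coalescent with
recombination (msprime) at mutation–drift equilibrium, giving the founders
realistic background linkage disequilibrium; the forward phase then adds
drift, migration, recombination and hitchhiking. This hybrid replaces a
~4N-generation forward burn-in that would dominate runtime while producing
the same equilibrium state; a pure SFS-draw founder mode (linkage
equilibrium) remains available for frequency-only work. The ancestral state
of every site is the zero allele by construction, so emitted AA annotations
are exact; a configurable mislabeling rate corrupts them to probe ΔDAF
robustness.

Multi-species data are built as independent contigs per species (one sweep
target per shared ortholog group, at the center of that group's gene), with
gene `g` of every species joined into ortholog group `OG{g}`; a coordinate
map links site ranks across species to a common frame, each site mapped
independently with a configurable fraction. Networks are Erdős–Rényi with
an optional denser planted module; trait tables give trait_1 an additive
genotype effect at the swept SNP and leave the remaining traits as pure
noise.

### Desk-scale parameter choices

The canonical study conditions live in `convergescan.scenarios` and were
chosen once as a coherent desk-scale analogue of a livestock resequencing
cohort:

* **Neutral calibration** — 200 diploids per population, two 250 kb contigs
  with ~5k SNPs, 80 generations since the split, migration 1e-3/gen.
* **Sweep recovery** — 500 diploids per population, eight 125 kb contigs
  (~10k SNPs over 1 Mb, ~400 genes), s = 0.1 run to ≥98% highland
  frequency, migration 2e-4.
* **Six-species convergence** — six pseudo-species of 150 diploids per
  population, six 80 kb contigs with ~600 genes each; one focal ortholog
  group swept in three species plus five groups swept in species pairs. The
  sweeps here use s = 0.5 so fixation completes within a 50-generation
  split history: at reduced population size a long s = 0.1 fixation would
  require so much post-split drift (t/2N ≫ 0.1) that neutral fixed
  differences would swamp any outlier statistic — the detection-power
  question at s = 0.1 belongs to the single-species experiment.

Two scalings matter at small N. Per-region crossover probabilities are
chosen so that (i) a sweep lasting ~2·ln(2N)/s generations drags a long
intact haplotype (fragmentation scale well above the background LD scale)
while (ii) distant loci still decouple, keeping the sweep localized to a
fraction of the genome. And migration during a sweep must stay low: at
desk-scale N even m ~ 2e-3/gen returns the swept allele on recombined
lowland backgrounds fast enough to soften the sweep visibly.

What the simulator does **not** emulate: real demographic histories of the
six species (bottlenecks, expansions, domestication), background selection,
recombination-rate variation, genotyping error and imputation artifacts,
sex chromosomes, and realistic gene structure. Passing tests therefore show
that the statistics and tests behave as designed under a controlled model —
not that real cohorts would yield any particular gene list.

## Numerical and design notes

* All fractions/percentiles validate to (0, 1); window ≥ step > 0.
* Every random draw flows from one seed through named substreams
  (CRC32-hashed stage names into `SeedSequence`), so any run is
  bit-reproducible from (config, seed).
* XP-EHH peaks often sit on a SNP immediately beside the selected site
  rather than exactly on it: at the core itself the lowland sample is
  nearly monomorphic *ancestral*, which elevates lowland homozygosity at
  short range and slightly depresses the core's own log-ratio. Recovery
  checks for XP-EHH therefore evaluate the peak within 10 kb of the core;
  F_ST and ΔDAF are evaluated at the core SNP itself.
* Empirical p-values are add-one estimators, bounded below by
  1/(n_permutations + 1).
* Gene universes for the shared-PSG permutation default to each species'
  scored-gene list; the published top-1% set sizes imply per-species
  universes of roughly 100× the set size, of which ~10k genes map to
  one-to-one ortholog groups, and the analytic checks use that geometry.

## Known limitations

* The iFXD odds product has a heavy upper tail by construction (odds are
  bounded only by 2n); single-SNP genes can reach extreme gene scores,
  which is why `min_snps_per_gene` defaults to 3.
* The chi-square reported by `compare_shared_counts` is one declared
  construction among several possible for a pair of shared counts.
* The exact Mann–Whitney branch requires tie-free samples; tied small
  samples fall back to the corrected normal approximation.
* Sites with residual missing genotypes are assumed imputed upstream; the
  readers reject records they cannot interpret rather than guessing.
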