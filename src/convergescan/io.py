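"""Readers and writers for every external format the pipeline touches.

External files use 1-based inclusive coordinates (VCF convention); conversion
to the half-open 0-based intervals used internally happens only here. The
parsers never drop records silently: rejected + retained = input, and every
rejection reason is counted and logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import SitePanel

logger = logging.getLogger("convergescan")

__all__ = [
    "read_panel", "read_pop_assignment", "read_table", "write_scores",
    "read_scores", "write_vcf", "TABLE_SCHEMAS",
]

#: Required columns per table schema.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "orthologs": ["species", "gene_id", "ortholog_group"],
    "coordinate_map": ["species", "chrom", "pos", "ref_chrom", "ref_pos"],
    "network_edges": ["gene_a", "gene_b"],
    "gene_set": ["set_name", "ortholog_group"],
    "traits": ["individual", "genotype", "elevation_class"],
    "annotation": ["snp_id", "chrom", "pos", "gene_id", "class"],
}

FUNC_CLASSES = frozenset({
    "nonsynonymous", "synonymous", "splicing", "utr5", "utr3",
    "intronic", "upstream", "downstream", "intergenic",
})


def read_pop_assignment(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (individual, population) mapping samples to
    highland/lowland."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"individual", "population"} <= set(df.columns):
        raise ValueError("population file needs columns individual, population")
    bad = set(df["population"]) - {"highland", "lowland"}
    if bad:
        raise ValueError(f"unknown population labels: {sorted(bad)}")
    return dict(zip(df["individual"], df["population"]))


def read_panel(
    vcf_path: str | Path,
    pop_assignment: dict[str, str],
    annotation_path: str | Path | None = None,
    species: str = "species",
) -> SitePanel:
    """Read a phased biallelic VCF into a :class:`SitePanel`.

    Every sample must be assigned to exactly one of {highland, lowland}.
    Multiallelic or unphased records are rejected (counted, logged); records
    whose INFO/AA ancestral allele is missing or matches neither REF nor ALT
    are retained but flagged unpolarized.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_assignment]
    if unknown:
        raise ValueError(f"samples not in population assignment: {unknown}")
    bad_pop = {s: p for s, p in pop_assignment.items()
               if p not in ("highland", "lowland")}
    if bad_pop:
        raise ValueError(f"invalid population labels: {bad_pop}")
    hi_idx = [i for i, s in enumerate(samples) if pop_assignment[s] == "highland"]
    lo_idx = [i for i, s in enumerate(samples) if pop_assignment[s] == "lowland"]

    chroms, pos, snp_id, ref, alt = [], [], [], [], []
    polarized, derived_is_alt = [], []
    hap_rows = []
    n_multi = n_unphased = n_unpolarized = 0
    n_input = 0
    for rec in vcf:
        n_input += 1
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotype.array()  # (n_samples, 3): a0, a1, phased flag
        if not np.all(gts[:, 2]):
            n_unphased += 1
            continue
        alleles = gts[:, :2]
        if alleles.min() < 0 or alleles.max() > 1:
            n_multi += 1  # missing or non-biallelic coding
            continue
        aa = rec.INFO.get("AA")
        aa = aa.upper() if isinstance(aa, str) else None
        if aa == rec.REF:
            polarized.append(True)
            derived_is_alt.append(True)
        elif aa == rec.ALT[0]:
            polarized.append(True)
            derived_is_alt.append(False)
        else:
            if aa is not None:
                logger.warning("AA=%s at %s:%d matches neither REF nor ALT; "
                               "flagged unpolarized", aa, rec.CHROM, rec.POS)
            polarized.append(False)
            derived_is_alt.append(True)
            n_unpolarized += 1
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        snp_id.append(rec.ID if rec.ID not in (None, ".") else
                      f"{rec.CHROM}_{rec.POS}")
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        hap_rows.append(alleles.reshape(-1))  # 2 haplotypes per sample

    n_kept = len(pos)
    logger.info("read_panel(%s): %d records in, %d kept, %d multiallelic/"
                "missing rejected, %d unphased rejected, %d unpolarized",
                vcf_path, n_input, n_kept, n_multi, n_unphased, n_unpolarized)
    if n_kept == 0:
        raise ValueError(f"no usable records in {vcf_path}")
    hap = np.array(hap_rows, dtype=np.uint8).T  # (2*n_samples, n_sites)
    hap_by_sample = hap.reshape(len(samples), 2, n_kept)
    hap_high = hap_by_sample[hi_idx].reshape(-1, n_kept)
    hap_low = hap_by_sample[lo_idx].reshape(-1, n_kept)

    panel = SitePanel(
        species=species,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        snp_id=np.array(snp_id, dtype=object),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        polarized=np.array(polarized, dtype=bool),
        derived_is_alt=np.array(derived_is_alt, dtype=bool),
        hap_high=hap_high,
        hap_low=hap_low,
        samples_high=[samples[i] for i in hi_idx],
        samples_low=[samples[i] for i in lo_idx],
        meta={"n_input": n_input, "n_rejected_multiallelic": n_multi,
              "n_rejected_unphased": n_unphased},
    )
    if annotation_path is not None:
        panel.annotate(read_table(annotation_path, "annotation"))
    return panel


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one of the pipeline's TSV inputs.

    Schemas: orthologs (one-to-one enforced), coordinate_map, network_edges
    (deduplicated, self-loops dropped), gene_set, traits, annotation.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} "
                         f"for schema {schema!r}")

    if schema == "orthologs":
        for key in ("gene_id", "ortholog_group"):
            dup = df.duplicated(subset=["species", key])
            if dup.any():
                bad = df.loc[dup, key].iloc[0]
                raise ValueError(f"{path}: {key} {bad!r} mapped more than once "
                                 "within a species (one-to-one contract)")
    elif schema == "network_edges":
        n_in = len(df)
        df = df[df["gene_a"] != df["gene_b"]]
        n_self = n_in - len(df)
        a = df[["gene_a", "gene_b"]].to_numpy(dtype=object)
        lo = np.minimum(a[:, 0], a[:, 1])
        hi = np.maximum(a[:, 0], a[:, 1])
        df = pd.DataFrame({"gene_a": lo, "gene_b": hi}).drop_duplicates()
        n_dup = n_in - n_self - len(df)
        logger.info("read_table(network_edges): %d in, %d self-loops dropped, "
                    "%d duplicates dropped, %d kept", n_in, n_self, n_dup, len(df))
        if n_in > 0 and len(df) == 0:
            raise ValueError(f"{path}: network contains only self-loops/duplicates")
        df = df.reset_index(drop=True)
    elif schema == "traits":
        if df["individual"].duplicated().any():
            raise ValueError(f"{path}: duplicated individual ids")
        if not df["genotype"].isin([0, 1, 2]).all():
            raise ValueError(f"{path}: genotype must be a 0/1/2 derived-allele count")
    elif schema == "annotation":
        bad = set(df["class"]) - FUNC_CLASSES
        if bad:
            raise ValueError(f"{path}: unknown functional classes {sorted(bad)}")
        df["gene_id"] = df["gene_id"].fillna("")
    return df


def trait_columns(traits: pd.DataFrame) -> list[str]:
    """Names of the quantitative trait columns of a traits table."""
    return [c for c in traits.columns
            if c not in ("individual", "genotype", "elevation_class")]


#: Fixed decimal precision for score tables (round-trip is bit-exact in text).
SCORE_FLOAT_FORMAT = "%.10g"


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write a SNP/gene/window score table as TSV (NA for missing values)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format=SCORE_FLOAT_FORMAT)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_vcf(panel: SitePanel, path: str | Path) -> None:
    """Write a :class:`SitePanel` as a phased VCF with INFO/AA ancestral
    alleles (the format :func:`read_panel` reads)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                 'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.chrom):
            mask = panel.chrom == chrom
            fh.write(f"##contig=<ID={chrom},length={int(panel.pos[mask].max()) + 1}>\n")
        samples = panel.samples_high + panel.samples_low
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        hap = np.vstack([panel.hap_high, panel.hap_low])
        for j in range(panel.n_sites):
            if panel.polarized[j]:
                aa = panel.ref[j] if panel.derived_is_alt[j] else panel.alt[j]
                info = f"AA={aa}"
            else:
                info = "AA=."
            gts = "\t".join(f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}"
                            for i in range(len(samples)))
            fh.write(f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_id[j]}\t"
                     f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t{info}\tGT\t{gts}\n")
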