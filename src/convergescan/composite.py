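"""Composite iFXD scores: per-SNP odds products, gene and window averages,
and top-fraction outlier (PSG) calls.

Each differentiation statistic is converted to a selection probability Ps,
realized as the one-sided empirical mid-rank probability of the statistic
among all scored SNPs genome-wide: Ps = (r − 0.5)/n with r the ascending
mid-rank. Larger F_ST, XP-EHH or ΔDAF ⇒ larger Ps; the −0.5 offset keeps Ps
strictly inside (0, 1) so the odds Ps/(1 − Ps) are finite. The per-SNP
composite is

    iFXD = ∏ᵢ Psᵢ / (1 − Psᵢ)

over the methods available at that SNP (a SNP missing one method — an
unpolarized site, or a failed XP-EHH — contributes the product over the
remaining methods, with the method count recorded). Gene scores are the
arithmetic mean of SNP iFXD over SNPs in the gene body; the top fraction
(default 1%) of genes by mean iFXD are called positively selected (PSGs).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ps_rank", "ifxd_snp", "add_ifxd", "gene_ifxd", "call_outliers",
    "psg_set", "sliding_window_ifxd",
]


def ps_rank(values: np.ndarray) -> np.ndarray:
    """Upper-tail empirical mid-rank probability Ps = (r − 0.5)/n.

    NaNs are ignored (returned as NaN); ties share their mid-rank, so a
    constant vector maps to Ps = 0.5 everywhere.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n == 0:
        return out
    if n == 1:
        out[ok] = 0.5
        return out
    r = rankdata(values[ok], method="average")
    out[ok] = (r - 0.5) / n
    return out


def _odds(ps: np.ndarray) -> np.ndarray:
    return ps / (1.0 - ps)


def ifxd_snp(ps_fst, ps_xpehh, ps_ddaf) -> np.ndarray:
    """iFXD = product of Ps/(1−Ps) over the available (non-NaN) methods."""
    ps = np.vstack([np.asarray(p, dtype=float) for p in
                    (ps_fst, ps_xpehh, ps_ddaf)])
    odds = _odds(ps)
    odds = np.where(np.isfinite(odds), odds, 1.0)
    prod = np.prod(odds, axis=0)
    n_methods = np.isfinite(ps).sum(axis=0)
    prod = np.where(n_methods == 0, np.nan, prod)
    return prod if prod.ndim else float(prod)


def add_ifxd(snp_scores: pd.DataFrame) -> pd.DataFrame:
    """Attach Ps columns, the method count and iFXD to a SNP score table."""
    t = snp_scores.copy()
    t["ps_fst"] = ps_rank(t["fst"].to_numpy())
    t["ps_xpehh"] = ps_rank(t["xpehh_norm"].to_numpy())
    t["ps_ddaf"] = ps_rank(t["ddaf"].to_numpy())
    ps = t[["ps_fst", "ps_xpehh", "ps_ddaf"]].to_numpy()
    t["n_methods"] = np.isfinite(ps).sum(axis=1)
    t["ifxd"] = ifxd_snp(t["ps_fst"], t["ps_xpehh"], t["ps_ddaf"])
    return t


def gene_ifxd(snp_scores: pd.DataFrame, min_snps_per_gene: int = 3,
              top_fraction: float = 0.01) -> pd.DataFrame:
    """Gene score table: mean SNP iFXD per gene, rank, Ps and PSG call.

    SNPs with empty gene assignment or missing iFXD are ignored; genes with
    fewer than ``min_snps_per_gene`` scored SNPs are excluded (their count
    is reported via the ``n_excluded_genes`` attribute of the result).
    Genes mixing 2- and 3-method SNPs are flagged ``mixed_methods``.
    """
    t = snp_scores
    genic = t[(t["gene_id"] != "") & np.isfinite(t["ifxd"])]
    if len(genic) == 0:
        raise ValueError("no scored genic SNPs")
    grp = genic.groupby("gene_id", sort=True)
    table = pd.DataFrame({
        "gene_id": list(grp.groups),
        "n_snps": grp.size().to_numpy(),
        "ifxd_gene": grp["ifxd"].mean().to_numpy(),
        "mixed_methods": (grp["n_methods"].nunique() > 1).to_numpy(),
    })
    n_before = len(table)
    table = table[table["n_snps"] >= min_snps_per_gene].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError(f"no genes with >= {min_snps_per_gene} scored SNPs")
    table.attrs["n_excluded_genes"] = n_before - len(table)
    # rank 1 = highest gene iFXD; deterministic tie-break for reporting
    order = np.lexsort((table["gene_id"].to_numpy(),
                        -table["n_snps"].to_numpy(),
                        -table["ifxd_gene"].to_numpy()))
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    table["ps_gene"] = ps_rank(table["ifxd_gene"].to_numpy())
    table = call_outliers(table, top_fraction)
    return table


def call_outliers(gene_table: pd.DataFrame, top_fraction: float) -> pd.DataFrame:
    """Flag the ceil(top_fraction · n) highest-iFXD genes as PSGs.

    Boundary ties are broken deterministically by (higher iFXD, higher
    n_snps, lexicographic gene_id) — the ordering already baked into the
    ``rank`` column. If the set would be empty a warning-sized empty call is
    returned.
    """
    t = gene_table.copy()
    n_psg = math.ceil(top_fraction * len(t))
    t["is_psg"] = t["rank"] <= n_psg
    return t


def psg_set(gene_table: pd.DataFrame) -> set[str]:
    return set(gene_table.loc[gene_table["is_psg"], "gene_id"])


def sliding_window_ifxd(snp_scores: pd.DataFrame, window_bp: int = 50_000,
                        step_bp: int = 25_000) -> pd.DataFrame:
    """Mean SNP iFXD in sliding windows (half-open, 0-based, grid anchored
    at position 0 of each chromosome). Windows with no scored SNPs are
    reported with NaN; chromosomes with no SNPs emit no windows."""
    if window_bp < step_bp or step_bp <= 0:
        raise ValueError("require window_bp >= step_bp > 0")
    rows = []
    for chrom, sub in snp_scores.groupby("chrom", sort=True):
        pos0 = sub["pos"].to_numpy() - 1  # to 0-based
        vals = sub["ifxd"].to_numpy(dtype=float)
        if len(pos0) == 0:
            continue
        last_start = (int(pos0.max()) // step_bp) * step_bp
        for start in range(0, last_start + 1, step_bp):
            end = start + window_bp
            inside = (pos0 >= start) & (pos0 < end)
            v = vals[inside]
            v = v[np.isfinite(v)]
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "n_snps": int(len(v)),
                "ifxd_window": float(v.mean()) if len(v) else np.nan,
            })
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                        "ifxd_window"])
    vals = table["ifxd_window"].to_numpy(dtype=float) if len(table) else np.array([])
    rank = np.full(len(table), np.nan)
    ok = np.isfinite(vals)
    if ok.any():
        order = np.argsort(-vals[ok], kind="stable")
        r = np.empty(ok.sum(), dtype=float)
        r[order] = np.arange(1, ok.sum() + 1)
        rank[ok] = r
    table["rank"] = rank
    return table
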