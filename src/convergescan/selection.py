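"""Per-SNP differentiation statistics: F_ST, ΔDAF and XP-EHH.

F_ST is the Weir–Cockerham (1984) two-population single-SNP estimator
θ̂ = a/(a+b+c) applied to haplotype counts (the heterozygosity component c
vanishes for haploid data); negative estimates, which have no biological
interpretation, are clipped to 0.

ΔDAF is the derived-allele frequency in the highland sample minus that in
the lowland sample, defined only at sites polarized by the outgroup
ancestral allele.

XP-EHH is ln(iHH_highland / iHH_lowland), where iHH is the trapezoidal
integral of extended haplotype homozygosity (EHH) over physical distance
from the core SNP. EHH at distance x is the fraction of haplotype pairs
identical at every site from the core out to x, computed on the full
population sample. Integration in both populations stops where the *pooled*
two-population EHH first drops below the cutoff (linearly interpolated), so
both populations are integrated over identical intervals and the ratio is
not biased by unequal truncation. Distances are physical bp throughout — no
genetic map. Raw scores are standardized genome-wide (mean 0, sd 1 over all
scored SNPs); positive values mean longer highland haplotypes, the signature
of a highland sweep.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .panel import SitePanel

__all__ = [
    "fst_wc", "ddaf", "ehh_curve", "ihh_one_side", "ihh", "xpehh_site",
    "xpehh", "score_panel",
]


# ---------------------------------------------------------------------------
# F_ST and ΔDAF


def fst_wc(n_high: np.ndarray, d_high: np.ndarray,
           n_low: np.ndarray, d_low: np.ndarray) -> np.ndarray:
    """Weir–Cockerham θ̂ per SNP from haplotype counts.

    Parameters are (haplotype count, derived/ALT count) per population;
    all four accept scalars or equal-length arrays. Returns NaN where a
    population has fewer than 2 haplotypes or the pooled site is
    monomorphic; negative estimates are set to 0.
    """
    n1 = np.asarray(n_high, dtype=float)
    n2 = np.asarray(n_low, dtype=float)
    p1 = np.divide(d_high, n1, out=np.zeros_like(n1), where=n1 > 0)
    p2 = np.divide(d_low, n2, out=np.zeros_like(n2), where=n2 > 0)
    nt = n1 + n2
    nbar = nt / 2.0
    pbar = (n1 * p1 + n2 * p2) / nt
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # r-1 = 1
    nc = nt - (n1 ** 2 + n2 ** 2) / nt
    qbar = pbar * (1.0 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (s2 - (qbar - s2 / 2.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (qbar - s2 / 2.0)
        theta = a / (a + b)
    theta = np.where(np.asarray(a + b) == 0.0, np.nan, theta)
    pooled = (np.asarray(d_high) + np.asarray(d_low)) / nt
    theta = np.where((pooled <= 0) | (pooled >= 1), np.nan, theta)
    theta = np.where((n1 < 2) | (n2 < 2), np.nan, theta)
    return np.clip(theta, 0.0, 1.0)


def ddaf(panel: SitePanel) -> pd.DataFrame:
    """Derived allele frequencies and their highland−lowland difference.

    Unpolarized sites get NaN in all three columns (they stay in the panel
    for F_ST and XP-EHH but are excluded from ΔDAF ranking)."""
    daf_high = panel.derived_freq("high")
    daf_low = panel.derived_freq("low")
    return pd.DataFrame({
        "snp_id": panel.snp_id,
        "daf_high": daf_high,
        "daf_low": daf_low,
        "ddaf": daf_high - daf_low,
    })


# ---------------------------------------------------------------------------
# EHH / iHH (reference implementations, used directly on small panels and as
# the slow path the scan kernel is checked against)


def ehh_curve(haplotypes: np.ndarray, positions: np.ndarray, core_index: int,
              direction: str) -> np.ndarray:
    """EHH curve from a core SNP outward in one direction.

    Returns an array of (distance_bp, ehh) rows, starting at distance 0
    (core site included). EHH(x) is the number of haplotype pairs identical
    over every site from the core out to x, divided by C(n, 2)."""
    n = haplotypes.shape[0]
    if n < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    step = 1 if direction == "right" else -1
    cols = range(core_index, haplotypes.shape[1] if step == 1 else -1, step)
    npairs = n * (n - 1) / 2.0
    out = []
    codes = np.zeros(n, dtype=np.int64)
    for j in cols:
        _, codes = np.unique(codes * 2 + haplotypes[:, j], return_inverse=True)
        counts = np.bincount(codes)
        same = float((counts * (counts - 1) // 2).sum())
        out.append((abs(float(positions[j] - positions[core_index])),
                    same / npairs))
    return np.asarray(out, dtype=float)


def _merge_duplicate_distances(curve: np.ndarray) -> np.ndarray:
    """Collapse repeated distances (keep the last, i.e. most-refined, EHH)."""
    if len(curve) < 2:
        return curve
    keep = np.append(np.diff(curve[:, 0]) != 0, True)
    return curve[keep]


def ihh_one_side(curve: np.ndarray, cutoff: float = 0.05) -> tuple[float, bool]:
    """Trapezoidal integral of one EHH curve, truncated at the first
    (linearly interpolated) crossing of ``cutoff``.

    Returns (integral in bp, reached_end) where reached_end is True when the
    curve ended before EHH fell below the cutoff (edge truncation)."""
    curve = _merge_duplicate_distances(np.asarray(curve, dtype=float))
    total = 0.0
    x0, y0 = curve[0]
    if y0 < cutoff:
        return 0.0, False
    for x1, y1 in curve[1:]:
        if y1 >= cutoff:
            total += 0.5 * (y0 + y1) * (x1 - x0)
            x0, y0 = x1, y1
        else:
            xs = x0 + (x1 - x0) * (y0 - cutoff) / (y0 - y1)
            ys = cutoff
            total += 0.5 * (y0 + ys) * (xs - x0)
            return total, False
    return total, True


def ihh(curve_left: np.ndarray, curve_right: np.ndarray,
        cutoff: float = 0.05) -> tuple[float, bool]:
    """Two-sided integrated EHH: the sum of both one-sided integrals.

    The edge flag is set if either side ran off the chromosome before the
    EHH cutoff was reached."""
    left, edge_l = ihh_one_side(curve_left, cutoff)
    right, edge_r = ihh_one_side(curve_right, cutoff)
    return left + right, edge_l or edge_r


def _interp(x0, y0, x1, y1, x):
    return y0 + (y1 - y0) * (x - x0) / (x1 - x0) if x1 != x0 else y1


def xpehh_site(hap_high: np.ndarray, hap_low: np.ndarray,
               positions: np.ndarray, core_index: int,
               cutoff: float = 0.05,
               max_extend: float = np.inf) -> tuple[float, float, bool]:
    """(iHH_high, iHH_low, edge_truncated) at one core SNP, with the
    integration limit set where the pooled-sample EHH crosses ``cutoff``
    (or at ``max_extend`` bp, whichever comes first).

    Reference implementation; the vectorized scan kernel must agree with it
    to float precision."""
    pooled = np.vstack([hap_high, hap_low])
    tot_hi = tot_lo = 0.0
    edge = False
    for direction in ("left", "right"):
        cp = ehh_curve(pooled, positions, core_index, direction)
        ch = ehh_curve(hap_high, positions, core_index, direction)
        cl = ehh_curve(hap_low, positions, core_index, direction)
        cp, ch, cl = (_merge_duplicate_distances(c) for c in (cp, ch, cl))
        if cp[0, 1] < cutoff:
            continue
        crossed = False
        for k in range(1, len(cp)):
            x0, y0 = cp[k - 1]
            x1, y1 = cp[k]
            if y1 >= cutoff and x1 > max_extend:
                yh = _interp(x0, ch[k - 1, 1], x1, ch[k, 1], max_extend)
                yl = _interp(x0, cl[k - 1, 1], x1, cl[k, 1], max_extend)
                tot_hi += 0.5 * (ch[k - 1, 1] + yh) * (max_extend - x0)
                tot_lo += 0.5 * (cl[k - 1, 1] + yl) * (max_extend - x0)
                edge = True
                crossed = True
                break
            if y1 >= cutoff:
                tot_hi += 0.5 * (ch[k - 1, 1] + ch[k, 1]) * (x1 - x0)
                tot_lo += 0.5 * (cl[k - 1, 1] + cl[k, 1]) * (x1 - x0)
            else:
                xs = x0 + (x1 - x0) * (y0 - cutoff) / (y0 - y1)
                yh = _interp(x0, ch[k - 1, 1], x1, ch[k, 1], xs)
                yl = _interp(x0, cl[k - 1, 1], x1, cl[k, 1], xs)
                tot_hi += 0.5 * (ch[k - 1, 1] + yh) * (xs - x0)
                tot_lo += 0.5 * (cl[k - 1, 1] + yl) * (xs - x0)
                crossed = True
                break
        if not crossed:
            edge = True
    return tot_hi, tot_lo, edge


# ---------------------------------------------------------------------------
# Fast chromosome scan (numba)


@njit(cache=True)
def _xpehh_walk_fast(indptr, carriers, n_hap, n_high, pos, cutoff, max_extend,
                     g, cnt_hi, cnt_lo, touched_old, saved_hi, saved_lo,
                     newid, stamp):  # pragma: no cover (numba)
    """Incremental partition-refinement XP-EHH scan.

    ``carriers``/``indptr`` hold, per column, the rows carrying that
    column's minor allele (CSR layout). Each walk refines the haplotype
    partition by moving only those rows into split-off groups and updates
    the identical-pair counts by difference, so a step costs O(carriers)
    instead of O(n_hap). Work buffers are caller-allocated and reused."""
    S = len(indptr) - 1
    n_low = n_hap - n_high
    ihh_hi = np.zeros(S)
    ihh_lo = np.zeros(S)
    edge = np.zeros(S, np.uint8)
    cpairs_hi = n_high * (n_high - 1) / 2.0
    cpairs_lo = n_low * (n_low - 1) / 2.0
    cpairs_all = n_hap * (n_hap - 1) / 2.0
    stamp[:] = -1
    step_counter = 0
    for c in range(S):
        for direction in range(2):
            step = 1 if direction == 0 else -1
            # reset partition: everyone in group 0
            for i in range(n_hap):
                g[i] = 0
            cnt_hi[0] = n_high
            cnt_lo[0] = n_low
            ngroups = 1
            same_h = cpairs_hi
            same_l = cpairs_lo
            same_p = cpairs_all
            prev_x = 0.0
            prev_p = prev_h = prev_l = 1.0
            j = c
            first = True
            while True:
                if ngroups > n_hap:
                    # compact group ids to a dense range (live groups <= n_hap)
                    step_counter += 1
                    dense = 0
                    for i in range(n_hap):
                        old = g[i]
                        if stamp[old] != step_counter:
                            stamp[old] = step_counter
                            newid[old] = dense
                            saved_hi[dense] = cnt_hi[old]
                            saved_lo[dense] = cnt_lo[old]
                            dense += 1
                        g[i] = newid[old]
                    for q in range(dense):
                        cnt_hi[q] = saved_hi[q]
                        cnt_lo[q] = saved_lo[q]
                    ngroups = dense
                step_counter += 1
                n_touched = 0
                for ci in range(indptr[j], indptr[j + 1]):
                    row = carriers[ci]
                    old = g[row]
                    if stamp[old] != step_counter:
                        stamp[old] = step_counter
                        newid[old] = ngroups
                        cnt_hi[ngroups] = 0
                        cnt_lo[ngroups] = 0
                        touched_old[n_touched] = old
                        saved_hi[n_touched] = cnt_hi[old]
                        saved_lo[n_touched] = cnt_lo[old]
                        n_touched += 1
                        ngroups += 1
                    nid = newid[old]
                    g[row] = nid
                    if row < n_high:
                        cnt_hi[old] -= 1
                        cnt_hi[nid] += 1
                    else:
                        cnt_lo[old] -= 1
                        cnt_lo[nid] += 1
                # update pair sums for affected groups
                for t in range(n_touched):
                    old = touched_old[t]
                    nid = newid[old]
                    oh = saved_hi[t]
                    ol = saved_lo[t]
                    same_h += (cnt_hi[old] * (cnt_hi[old] - 1)
                               + cnt_hi[nid] * (cnt_hi[nid] - 1)
                               - oh * (oh - 1)) / 2.0
                    same_l += (cnt_lo[old] * (cnt_lo[old] - 1)
                               + cnt_lo[nid] * (cnt_lo[nid] - 1)
                               - ol * (ol - 1)) / 2.0
                    ot = oh + ol
                    nt1 = cnt_hi[old] + cnt_lo[old]
                    nt2 = cnt_hi[nid] + cnt_lo[nid]
                    same_p += (nt1 * (nt1 - 1) + nt2 * (nt2 - 1)
                               - ot * (ot - 1)) / 2.0
                e_p = same_p / cpairs_all
                e_h = same_h / cpairs_hi if cpairs_hi > 0 else 0.0
                e_l = same_l / cpairs_lo if cpairs_lo > 0 else 0.0
                x = abs(float(pos[j] - pos[c]))
                if first:
                    first = False
                    if e_p < cutoff:
                        break
                    prev_x, prev_p, prev_h, prev_l = x, e_p, e_h, e_l
                else:
                    if e_p >= cutoff and x > max_extend:
                        if x != prev_x:
                            frac = (max_extend - prev_x) / (x - prev_x)
                        else:
                            frac = 1.0
                        yh = prev_h + (e_h - prev_h) * frac
                        yl = prev_l + (e_l - prev_l) * frac
                        ihh_hi[c] += 0.5 * (prev_h + yh) * (max_extend - prev_x)
                        ihh_lo[c] += 0.5 * (prev_l + yl) * (max_extend - prev_x)
                        edge[c] = 1
                        break
                    if e_p >= cutoff:
                        ihh_hi[c] += 0.5 * (prev_h + e_h) * (x - prev_x)
                        ihh_lo[c] += 0.5 * (prev_l + e_l) * (x - prev_x)
                        prev_x, prev_p, prev_h, prev_l = x, e_p, e_h, e_l
                    else:
                        xs = prev_x + (x - prev_x) * (prev_p - cutoff) / (prev_p - e_p)
                        if x != prev_x:
                            frac = (xs - prev_x) / (x - prev_x)
                        else:
                            frac = 1.0
                        yh = prev_h + (e_h - prev_h) * frac
                        yl = prev_l + (e_l - prev_l) * frac
                        ihh_hi[c] += 0.5 * (prev_h + yh) * (xs - prev_x)
                        ihh_lo[c] += 0.5 * (prev_l + yl) * (xs - prev_x)
                        break
                j += step
                if j < 0 or j >= S:
                    edge[c] = 1
                    break
    return ihh_hi, ihh_lo, edge


def xpehh(panel: SitePanel, cutoff: float = 0.05,
          max_extend_bp: float = 500_000.0) -> pd.DataFrame:
    """XP-EHH per SNP (raw log-ratio and genome-wide standardized value).

    Chromosomes/contigs are scanned independently. SNPs where either
    population's iHH is 0 are flagged missing; sites where the integration
    hit a chromosome end or the ``max_extend_bp`` limit before the EHH
    cutoff carry ``edge_truncated``. The extension cap bounds the walk in
    saturated regions (e.g. around a fixed sweep, where pooled EHH can never
    fall below the cutoff because the swept population contributes a fixed
    fraction of identical pairs).
    """
    n_sites = panel.n_sites
    n_hap = panel.n_hap_high + panel.n_hap_low
    ihh_hi = np.empty(n_sites)
    ihh_lo = np.empty(n_sites)
    edge = np.zeros(n_sites, dtype=bool)
    # reusable work buffers for the refinement walk
    g = np.empty(n_hap, np.int64)
    cnt_hi = np.zeros(2 * n_hap + 2, np.int64)
    cnt_lo = np.zeros(2 * n_hap + 2, np.int64)
    touched = np.empty(n_hap + 1, np.int64)
    saved_hi = np.empty(2 * n_hap + 2, np.int64)
    saved_lo = np.empty(2 * n_hap + 2, np.int64)
    newid = np.empty(2 * n_hap + 2, np.int64)
    stamp = np.empty(2 * n_hap + 2, np.int64)
    for chrom in pd.unique(panel.chrom):
        mask = panel.chrom == chrom
        H = np.vstack([panel.hap_high[:, mask], panel.hap_low[:, mask]])
        # minor-allele carriers per column, CSR layout
        ones = H.sum(axis=0)
        minor = np.where(2 * ones <= n_hap, 1, 0).astype(np.uint8)
        M = (H == minor[None, :])
        cols, rows = np.nonzero(M.T)
        counts = np.bincount(cols, minlength=H.shape[1])
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        hi, lo, ed = _xpehh_walk_fast(
            indptr, rows.astype(np.int64), n_hap, panel.n_hap_high,
            panel.pos[mask].astype(np.float64), cutoff, float(max_extend_bp),
            g, cnt_hi, cnt_lo, touched, saved_hi, saved_lo, newid, stamp)
        ihh_hi[mask] = hi
        ihh_lo[mask] = lo
        edge[mask] = ed.astype(bool)
    ok = (ihh_hi > 0) & (ihh_lo > 0)
    raw = np.full(n_sites, np.nan)
    raw[ok] = np.log(ihh_hi[ok] / ihh_lo[ok])
    norm = np.full(n_sites, np.nan)
    if ok.sum() >= 2:
        sd = raw[ok].std()
        if sd > 0:
            norm[ok] = (raw[ok] - raw[ok].mean()) / sd
        else:
            norm[ok] = 0.0
    return pd.DataFrame({
        "snp_id": panel.snp_id,
        "ihh_high": ihh_hi, "ihh_low": ihh_lo,
        "xpehh_raw": raw, "xpehh_norm": norm,
        "edge_truncated": edge, "xpehh_missing": ~ok,
    })


# ---------------------------------------------------------------------------
# Full scan


def score_panel(panel: SitePanel, ehh_cutoff: float = 0.05,
                max_extend_bp: float = 500_000.0) -> pd.DataFrame:
    """The per-SNP score table: F_ST, DAFs, ΔDAF, XP-EHH and flags.

    Pooled-monomorphic sites are flagged and carry NaN everywhere (they are
    excluded from all downstream ranking); unpolarized sites lose only ΔDAF.
    """
    n_hi = panel.n_hap_high
    n_lo = panel.n_hap_low
    d_hi = panel.hap_high.sum(axis=0).astype(float)
    d_lo = panel.hap_low.sum(axis=0).astype(float)
    pooled = d_hi + d_lo
    monomorphic = (pooled == 0) | (pooled == n_hi + n_lo)
    fst = fst_wc(np.full_like(d_hi, n_hi), d_hi, np.full_like(d_lo, n_lo), d_lo)
    daf = ddaf(panel)
    xp = xpehh(panel, cutoff=ehh_cutoff, max_extend_bp=max_extend_bp)
    table = pd.DataFrame({
        "snp_id": panel.snp_id,
        "chrom": panel.chrom,
        "pos": panel.pos,
        "gene_id": panel.gene_id if panel.gene_id is not None
                   else np.full(panel.n_sites, "", dtype=object),
        "class": panel.func_class if panel.func_class is not None
                 else np.full(panel.n_sites, "intergenic", dtype=object),
        "fst": fst,
        "daf_high": daf["daf_high"],
        "daf_low": daf["daf_low"],
        "ddaf": daf["ddaf"],
        "xpehh_raw": xp["xpehh_raw"],
        "xpehh_norm": xp["xpehh_norm"],
        "monomorphic": monomorphic,
        "unpolarized": ~panel.polarized,
        "edge_truncated": xp["edge_truncated"],
        "xpehh_missing": xp["xpehh_missing"],
    })
    for col in ("fst", "daf_high", "daf_low", "ddaf", "xpehh_raw", "xpehh_norm"):
        table.loc[monomorphic, col] = np.nan
    table.loc[~panel.polarized, ["daf_high", "daf_low", "ddaf"]] = np.nan
    # re-standardize XP-EHH over the scored (non-monomorphic) SNPs only
    raw = table["xpehh_raw"].to_numpy()
    ok = np.isfinite(raw)
    norm = np.full(len(raw), np.nan)
    if ok.sum() >= 2 and raw[ok].std() > 0:
        norm[ok] = (raw[ok] - raw[ok].mean()) / raw[ok].std()
    elif ok.sum() >= 1:
        norm[ok] = 0.0
    table["xpehh_norm"] = norm
    return table
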