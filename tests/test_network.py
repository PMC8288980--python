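"""Interaction-ratio enrichment, Mann–Whitney U, gene-set and class scans."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from convergescan.network import (annotation_class_diff, geneset_scan,
                                  high_fst_functional_snps,
                                  interaction_ratio_between,
                                  interaction_ratio_within, mann_whitney_u,
                                  ratio_null)


def edges(*pairs):
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


class TestInteractionRatios:
    def test_within_formula(self):
        # one edge among three genes: R = 1 / (3*2)
        assert interaction_ratio_within({"A", "B", "C"}, edges(("A", "B"))) \
            == pytest.approx(1 / 6)

    def test_within_complete_graph_max_half(self):
        genes = {"A", "B", "C", "D"}
        net = edges(*itertools.combinations(sorted(genes), 2))
        assert interaction_ratio_within(genes, net) == pytest.approx(0.5)

    def test_within_empty_network(self):
        assert interaction_ratio_within({"A", "B"}, edges()) == 0.0

    def test_within_needs_two(self):
        with pytest.raises(ValueError):
            interaction_ratio_within({"A"}, edges())

    def test_between_formula(self):
        assert interaction_ratio_between({"a1", "a2"}, {"b1"},
                                         edges(("a1", "b1"))) == 0.5

    def test_between_no_cross_edges(self):
        assert interaction_ratio_between({"a"}, {"b"}, edges(("a", "a2"))) == 0.0

    def test_between_complete_bipartite(self):
        A = {"a1", "a2"}
        B = {"b1", "b2", "b3"}
        net = edges(*[(a, b) for a in sorted(A) for b in sorted(B)])
        assert interaction_ratio_between(A, B, net) == pytest.approx(1.0)


class TestRatioNull:
    def test_er_within_mean_is_half_p(self):
        """On an Erdos-Renyi(p) network, the mean simulated within-ratio is
        p/2 under the ordered-pair denominator convention."""
        rng = np.random.default_rng(0)
        n, p = 200, 0.08
        nodes = [f"G{i}" for i in range(n)]
        ia, ib = np.triu_indices(n, k=1)
        keep = rng.random(len(ia)) < p
        net = pd.DataFrame({"gene_a": np.array(nodes)[ia[keep]],
                            "gene_b": np.array(nodes)[ib[keep]]})
        res = ratio_null({"x": set(nodes[:25])}, nodes, net,
                         n_permutations=400, rng=np.random.default_rng(1))
        got = res["within"]["x"]["null_mean"]
        assert got == pytest.approx(p / 2, rel=0.15)

    def test_planted_module_detected(self):
        rng = np.random.default_rng(2)
        nodes = [f"G{i}" for i in range(80)]
        module = set(nodes[:10])
        ia, ib = np.triu_indices(80, k=1)
        in_mod = np.isin(np.array(nodes)[ia], list(module)) \
            & np.isin(np.array(nodes)[ib], list(module))
        keep = rng.random(len(ia)) < np.where(in_mod, 0.8, 0.02)
        net = pd.DataFrame({"gene_a": np.array(nodes)[ia[keep]],
                            "gene_b": np.array(nodes)[ib[keep]]})
        res = ratio_null({"x": module}, nodes, net, n_permutations=199,
                         rng=np.random.default_rng(3))
        assert res["within"]["x"]["observed"] > res["within"]["x"]["null_mean"]
        assert res["within"]["x"]["p_value"] < 0.05

    def test_p_value_floor(self):
        nodes = [f"G{i}" for i in range(20)]
        net = edges(("G0", "G1"))
        res = ratio_null({"x": {"G0", "G1"}}, nodes, net, n_permutations=49,
                         rng=np.random.default_rng(4))
        assert res["within"]["x"]["p_value"] >= 1 / 50

    def test_between_symmetric_in_order(self):
        rng = np.random.default_rng(5)
        nodes = [f"G{i}" for i in range(40)]
        ia, ib = np.triu_indices(40, k=1)
        keep = rng.random(len(ia)) < 0.1
        net = pd.DataFrame({"gene_a": np.array(nodes)[ia[keep]],
                            "gene_b": np.array(nodes)[ib[keep]]})
        sets = {"a": set(nodes[:8]), "b": set(nodes[8:16])}
        r1 = ratio_null(sets, nodes, net, 99, rng=np.random.default_rng(6))
        got = r1["between"]["a|b"]["observed"]
        assert got == interaction_ratio_between(sets["b"], sets["a"], net)


def exhaustive_mwu_p(a, b):
    """Exact two-sided p by enumerating all C(n, na) group assignments."""
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - na * (na + 1) / 2

    u_obs = u_of(range(na))
    mu = na * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        u = u_of(idx)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_separated_triples(self):
        u, z, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        u, z, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_extreme_separation(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 400)
        b = rng.normal(10, 1, 400)
        _, z, p = mann_whitney_u(a, b)
        assert p < 1e-10 and z < 0

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            _, _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(exhaustive_mwu_p(a, b), abs=1e-9)

    def test_branch_boundary_agreement(self):
        """Exact and normal-approximation p agree to ~0.01 at the sizes
        where the implementation switches branches."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.normal(size=10)
            b = rng.normal(size=20)  # na*nb = 200 -> exact branch
            _, _, p_exact = mann_whitney_u(a, b)
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic", use_continuity=True)
            assert abs(p_exact - res.pvalue) < 0.01

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def toy_scores(rng, n=600, n_genes=30, planted=None):
    gene_id = rng.choice([f"g{i:02d}" for i in range(n_genes)], size=n)
    cls = rng.choice(["nonsynonymous", "synonymous", "intronic"], size=n,
                     p=[0.2, 0.3, 0.5])
    fst = rng.beta(0.5, 3, size=n)
    t = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "chrom": "1", "pos": np.arange(1, n + 1) * 50,
        "gene_id": gene_id, "class": cls,
        "fst": fst, "xpehh_norm": rng.normal(size=n),
        "ddaf": rng.uniform(-1, 1, size=n),
        "daf_high": rng.random(n), "daf_low": rng.random(n),
    })
    if planted:
        sel = t["gene_id"].isin(planted)
        t.loc[sel, ["fst"]] = rng.uniform(0.7, 1.0, size=int(sel.sum()))[:, None]
        t.loc[sel, "xpehh_norm"] += 3
        t.loc[sel, "ddaf"] = rng.uniform(0.7, 1.0, size=int(sel.sum()))
    return t


class TestGenesetScan:
    def test_planted_set_significant(self):
        rng = np.random.default_rng(10)
        planted = {"g00", "g01", "g02"}
        t = toy_scores(rng, planted=planted)
        rep = geneset_scan(t, {g.upper() for g in planted},
                           species_gene_map={f"g{i:02d}": f"G{i:02d}"
                                             for i in range(30)},
                           n_random=49, rng=np.random.default_rng(11))
        assert rep["per_statistic"]["fst"]["p_vs_genome"] < 0.01
        assert rep["per_statistic"]["fst"]["p_vs_random_median"] < 0.05
        assert rep["per_statistic"]["fst"]["p_empirical"] <= 0.05

    def test_set_covering_all_genes_error(self):
        rng = np.random.default_rng(12)
        t = toy_scores(rng)
        with pytest.raises(ValueError, match="no background"):
            geneset_scan(t, set(t["gene_id"].unique()), n_random=5)

    def test_unresolvable_set_error(self):
        rng = np.random.default_rng(13)
        t = toy_scores(rng)
        with pytest.raises(ValueError, match="resolves to no"):
            geneset_scan(t, {"NOPE"}, n_random=5)


class TestAnnotationClassDiff:
    def test_planted_nonsynonymous_elevation(self):
        rng = np.random.default_rng(14)
        t = toy_scores(rng, n=2000)
        nonsyn = t["class"] == "nonsynonymous"
        t.loc[nonsyn, "fst"] = rng.beta(3, 2, size=int(nonsyn.sum()))
        rep = annotation_class_diff(t)
        assert rep["per_class"]["nonsynonymous"]["median_fst"] \
            > rep["per_class"]["synonymous"]["median_fst"]
        assert rep["nonsynonymous_vs"]["synonymous"]["p_value"] < 0.01

    def test_single_class_error(self):
        rng = np.random.default_rng(15)
        t = toy_scores(rng)
        t["class"] = "intronic"
        with pytest.raises(ValueError, match="at least 2"):
            annotation_class_diff(t)


class TestHighFstFunctionalSnps:
    def test_planted_rows_survive_filter(self):
        rng = np.random.default_rng(16)
        t = toy_scores(rng, n=1000)
        t["fst"] = rng.uniform(0, 0.4, size=1000)
        planted = (t.index < 20)
        t.loc[planted, "fst"] = rng.uniform(0.6, 1.0, size=20)
        t.loc[planted, "class"] = "nonsynonymous"
        t.loc[planted, "gene_id"] = "g00"
        rep = high_fst_functional_snps(t, psg_genes={"g00"}, fst_threshold=0.5)
        assert rep["n_candidates"] == 20
        assert set(rep["table"]["snp_id"]) == set(t.loc[planted, "snp_id"])

    def test_impossible_threshold_empty(self):
        rng = np.random.default_rng(17)
        t = toy_scores(rng)
        rep = high_fst_functional_snps(t, psg_genes=set(t["gene_id"]),
                                       fst_threshold=1.01)
        assert rep["n_candidates"] == 0

    def test_fixed_difference_row(self):
        rng = np.random.default_rng(18)
        t = toy_scores(rng, n=50)
        t.loc[0, ["fst", "daf_high", "class", "gene_id"]] = \
            [1.0, 1.0, "nonsynonymous", "g05"]
        rep = high_fst_functional_snps(t, psg_genes={"g05"})
        assert (rep["table"]["daf_high"] == 1.0).any()
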