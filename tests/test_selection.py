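"""Selection statistics against independent oracles.

The F_ST oracle is the haploid one-way ANOVA mean-square form of the
Weir–Cockerham estimator, an algebraically independent route from the
package's a/b variance-component implementation. The EHH oracle enumerates
haplotype pairs exhaustively; the iHH oracle re-implements trapezoid
integration with interpolated cutoff crossing from the curves.
"""

import itertools

import numpy as np
import pytest

from convergescan.selection import (ddaf, ehh_curve, fst_wc, ihh,
                                    ihh_one_side, score_panel, xpehh,
                                    xpehh_site)

from conftest import build_panel


# ---------------------------------------------------------------------------
# Independent oracles


def fst_anova_oracle(n1, d1, n2, d2):
    """WC84 theta via haploid ANOVA mean squares:
    theta = (MSP - MSG) / (MSP + (nc - 1) MSG)."""
    p1, p2 = d1 / n1, d2 / n2
    nt = n1 + n2
    pbar = (d1 + d2) / nt
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (2 - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nt - 2)
    nc = nt - (n1 ** 2 + n2 ** 2) / nt
    denom = msp + (nc - 1) * msg
    if denom == 0:
        return np.nan
    return max(0.0, (msp - msg) / denom)


def brute_ehh_curve(H, pos, core, direction):
    """Exhaustive pair counting at every cutpoint."""
    n = H.shape[0]
    npairs = n * (n - 1) / 2
    cols = (range(core, H.shape[1]) if direction == "right"
            else range(core, -1, -1))
    out = []
    span = []
    for j in cols:
        span.append(j)
        same = sum(1 for a, b in itertools.combinations(range(n), 2)
                   if np.array_equal(H[a, span], H[b, span]))
        out.append((abs(float(pos[j] - pos[core])), same / npairs))
    return np.array(out)


def brute_ihh_one_side(curve, cutoff):
    """Trapezoid with linear interpolation at the cutoff crossing."""
    total = 0.0
    if curve[0][1] < cutoff:
        return 0.0, False
    for (x0, y0), (x1, y1) in zip(curve[:-1], curve[1:]):
        if x1 == x0:
            continue
        if y1 >= cutoff:
            total += (y0 + y1) / 2 * (x1 - x0)
        else:
            xs = x0 + (x1 - x0) * (y0 - cutoff) / (y0 - y1)
            total += (y0 + cutoff) / 2 * (xs - x0)
            return total, False
    return total, True


def brute_xpehh_site(hh, hl, pos, core, cutoff=0.05):
    """Pooled-stop integration recomputed from brute-force curves."""
    pooled = np.vstack([hh, hl])
    tot = [0.0, 0.0]
    for direction in ("left", "right"):
        cp = brute_ehh_curve(pooled, pos, core, direction)
        ch = brute_ehh_curve(hh, pos, core, direction)
        cl = brute_ehh_curve(hl, pos, core, direction)
        if cp[0][1] < cutoff:
            continue
        for k in range(1, len(cp)):
            x0, x1 = cp[k - 1][0], cp[k][0]
            if cp[k][1] >= cutoff:
                tot[0] += (ch[k - 1][1] + ch[k][1]) / 2 * (x1 - x0)
                tot[1] += (cl[k - 1][1] + cl[k][1]) / 2 * (x1 - x0)
            else:
                xs = x0 + (x1 - x0) * (cp[k - 1][1] - cutoff) / (cp[k - 1][1] - cp[k][1])
                f = (xs - x0) / (x1 - x0) if x1 != x0 else 1.0
                yh = ch[k - 1][1] + (ch[k][1] - ch[k - 1][1]) * f
                yl = cl[k - 1][1] + (cl[k][1] - cl[k - 1][1]) * f
                tot[0] += (ch[k - 1][1] + yh) / 2 * (xs - x0)
                tot[1] += (cl[k - 1][1] + yl) / 2 * (xs - x0)
                break
    return tot


# ---------------------------------------------------------------------------


class TestFst:
    def test_complete_fixation(self):
        assert fst_wc(20, 20, 20, 0) == pytest.approx(1.0)

    def test_no_differentiation_clipped(self):
        assert fst_wc(20, 10, 20, 10) == 0.0

    def test_against_anova_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1 = int(rng.integers(4, 60))
            n2 = int(rng.integers(4, 60))
            d1 = int(rng.integers(0, n1 + 1))
            d2 = int(rng.integers(0, n2 + 1))
            if d1 + d2 == 0 or d1 + d2 == n1 + n2:
                continue
            got = float(fst_wc(n1, d1, n2, d2))
            want = fst_anova_oracle(n1, d1, n2, d2)
            assert got == pytest.approx(want, abs=1e-12)

    def test_monomorphic_nan(self):
        assert np.isnan(fst_wc(20, 0, 20, 0))
        assert np.isnan(fst_wc(20, 20, 20, 20))

    def test_tiny_sample_nan(self):
        assert np.isnan(fst_wc(1, 1, 20, 5))


class TestDdaf:
    def test_fixed_difference(self):
        panel = build_panel(np.ones((4, 1)), np.zeros((4, 1)))
        assert ddaf(panel)["ddaf"][0] == 1.0

    def test_published_horse_frequencies(self):
        # highland 0.79 vs lowland 0.28 derived frequency -> ΔDAF 0.51
        hh = np.zeros((100, 1), np.uint8)
        hh[:79] = 1
        hl = np.zeros((100, 1), np.uint8)
        hl[:28] = 1
        panel = build_panel(hh, hl)
        assert ddaf(panel)["ddaf"][0] == pytest.approx(0.51)

    def test_identical_populations(self):
        h = np.tile(np.array([[0], [1]], np.uint8), (2, 1))
        panel = build_panel(h, h.copy())
        assert ddaf(panel)["ddaf"][0] == 0.0

    def test_unpolarized_nan_and_ref_derived_flip(self):
        hh = np.array([[1], [1], [0], [0]], np.uint8)
        panel = build_panel(hh, hh.copy(),
                            polarized=np.array([True]),
                            derived_is_alt=np.array([False]))
        # derived = REF, so derived frequency = 1 - ALT frequency
        assert ddaf(panel)["daf_high"][0] == pytest.approx(0.5)
        panel2 = build_panel(hh, hh.copy(), polarized=np.array([False]))
        assert np.isnan(ddaf(panel2)["ddaf"][0])


class TestEhh:
    def test_identical_haplotypes(self):
        H = np.tile(np.array([[0, 1, 0, 1]], np.uint8), (5, 1))
        curve = ehh_curve(H, np.array([10, 20, 30, 40]), 1, "right")
        assert (curve[:, 1] == 1.0).all()

    def test_all_distinct_extension_drops_to_zero(self):
        # 4 haplotypes equal at the core, pairwise distinct at the flank
        H = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], np.uint8)
        curve = ehh_curve(H, np.array([10, 20, 30]), 0, "right")
        assert curve[0, 1] == 1.0
        assert curve[-1, 1] == 0.0

    def test_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            H = rng.integers(0, 2, (6, 10)).astype(np.uint8)
            pos = np.sort(rng.choice(1000, 10, replace=False))
            core = int(rng.integers(0, 10))
            for direction in ("left", "right"):
                got = ehh_curve(H, pos, core, direction)
                want = brute_ehh_curve(H, pos, core, direction)
                np.testing.assert_allclose(got, want, atol=1e-12)

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(2)
        H = rng.integers(0, 2, (8, 15)).astype(np.uint8)
        curve = ehh_curve(H, np.arange(15) * 10, 7, "right")
        assert (np.diff(curve[:, 1]) <= 1e-12).all()


class TestIhh:
    def test_rectangle_with_edge_flag(self):
        curve = np.array([[0, 1.0], [500, 1.0], [1000, 1.0]])
        val, edge = ihh(curve, curve, cutoff=0.05)
        assert val == pytest.approx(2000.0)
        assert edge

    def test_hand_trapezoid_with_interpolation(self):
        curve = np.array([[0, 1.0], [100, 0.5], [200, 0.04]])
        val, edge = ihh_one_side(curve, cutoff=0.05)
        xs = 100 + 100 * (0.5 - 0.05) / (0.5 - 0.04)
        expected = (1.0 + 0.5) / 2 * 100 + (0.5 + 0.05) / 2 * (xs - 100)
        assert val == pytest.approx(expected, abs=1e-10)
        assert not edge

    def test_symmetric_curves_double(self):
        curve = np.array([[0, 1.0], [100, 0.5], [200, 0.04]])
        both, _ = ihh(curve, curve)
        one, _ = ihh_one_side(curve)
        assert both == pytest.approx(2 * one)


class TestXpehh:
    def test_identical_panels_zero(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, (6, 12)).astype(np.uint8)
        panel = build_panel(H, H.copy())
        xp = xpehh(panel)
        ok = ~xp["xpehh_missing"]
        np.testing.assert_allclose(xp.loc[ok, "xpehh_raw"], 0.0, atol=1e-12)

    def test_homogeneous_highland_positive(self):
        rng = np.random.default_rng(4)
        hh = np.tile(rng.integers(0, 2, (1, 20)), (10, 1)).astype(np.uint8)
        hl = rng.integers(0, 2, (10, 20)).astype(np.uint8)
        panel = build_panel(hh, hl)
        xp = xpehh(panel)
        interior = xp["xpehh_raw"][5:15]
        assert (interior[np.isfinite(interior)] > 0).all()

    def test_brute_force_oracle_end_to_end(self):
        rng = np.random.default_rng(6)
        for trial in range(6):
            hh = rng.integers(0, 2, (5, 10)).astype(np.uint8)
            hl = rng.integers(0, 2, (5, 10)).astype(np.uint8)
            pos = np.sort(rng.choice(2000, 10, replace=False)) + 1
            panel = build_panel(hh, hl, positions=pos)
            xp = xpehh(panel)
            for c in range(10):
                want_hi, want_lo = brute_xpehh_site(hh, hl, pos, c)
                assert xp["ihh_high"][c] == pytest.approx(want_hi, abs=1e-10)
                assert xp["ihh_low"][c] == pytest.approx(want_lo, abs=1e-10)

    def test_fast_kernel_matches_reference_with_cap(self):
        rng = np.random.default_rng(7)
        hh = rng.integers(0, 2, (8, 25)).astype(np.uint8)
        hl = rng.integers(0, 2, (8, 25)).astype(np.uint8)
        pos = np.sort(rng.choice(5000, 25, replace=False)) + 1
        panel = build_panel(hh, hl, positions=pos)
        xp = xpehh(panel, max_extend_bp=800.0)
        for c in range(25):
            sh, sl, sedge = xpehh_site(hh, hl, pos, c, 0.05, max_extend=800.0)
            assert xp["ihh_high"][c] == pytest.approx(sh, abs=1e-10)
            assert xp["ihh_low"][c] == pytest.approx(sl, abs=1e-10)
            assert bool(xp["edge_truncated"][c]) == sedge


class TestScorePanel:
    def test_population_swap_symmetry(self, random_panel):
        s = score_panel(random_panel)
        t = score_panel(random_panel.swapped())
        np.testing.assert_allclose(s["fst"], t["fst"], atol=1e-12)
        np.testing.assert_allclose(s["ddaf"], -t["ddaf"], atol=1e-12)
        ok = np.isfinite(s["xpehh_raw"]) & np.isfinite(t["xpehh_raw"])
        np.testing.assert_allclose(s.loc[ok, "xpehh_raw"],
                                   -t.loc[ok, "xpehh_raw"], atol=1e-12)

    def test_norm_standardized(self, small_neutral_panel):
        s = score_panel(small_neutral_panel)
        x = s["xpehh_norm"].to_numpy()
        x = x[np.isfinite(x)]
        assert abs(x.mean()) < 1e-9
        assert abs(x.std() - 1.0) < 1e-9

    def test_sweep_signal_extreme(self, small_sweep_panel):
        panel, truth = small_sweep_panel
        s = score_panel(panel)
        j = np.nonzero(panel.snp_id == truth.swept_sites["species"])[0][0]
        for col in ("fst", "ddaf"):
            v = s[col].to_numpy()
            ok = np.isfinite(v)
            assert (v[ok] <= v[j]).mean() > 0.95

    def test_flags(self, random_panel):
        s = score_panel(random_panel)
        assert not s["monomorphic"].any()
        assert not s["unpolarized"].any()
        assert set(s.columns) >= {"fst", "ddaf", "xpehh_raw", "xpehh_norm",
                                  "daf_high", "daf_low"}
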