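import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tisig.simulate import simulate_composition
from tisig.stats import (dirichlet_regression, exact_ranksum_p, fisher_gwas_enrichment,
                         genes_near_snps, hypergeom_sf_logspace, overrepresentation_gmt,
                         tr_genes, wilcoxon_de)
from tisig.signatures import GeneSignature
from tisig.stats import _dirichlet_nll_grad

from .conftest import make_lognorm


def enum_ranksum_p(x, y):
    """Full permutation enumeration of the two-sided rank-sum p-value."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    ws = np.array([ranks[list(c)].sum()
                   for c in itertools.combinations(range(n), n1)])
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestExactRanksum:
    def test_textbook_separation(self):
        assert exact_ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(40):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            # small integer support forces ties
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
            assert exact_ranksum_p(x, y) == pytest.approx(enum_ranksum_p(x, y), abs=1e-12)

    def test_identical_groups_p_one(self):
        assert exact_ranksum_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_exact_close_to_asymptotic_at_n6(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.3, 1, 6)
            p_exact = exact_ranksum_p(x, y)
            p_asym = sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
            assert abs(p_exact - p_asym) <= 0.02


class TestWilcoxonDE:
    def _matrix(self, X1, X2):
        X = np.hstack([X1, X2])
        m = make_lognorm(X)
        g1 = list(m.cell_ids[: X1.shape[1]])
        g2 = list(m.cell_ids[X1.shape[1]:])
        return m, g1, g2

    def test_identical_groups_null(self):
        v = np.tile(np.linspace(0.5, 2, 5), (3, 1))
        m, g1, g2 = self._matrix(v, v)
        de = wilcoxon_de(m, g1, g2)
        assert (de.p_value == 1.0).all()
        np.testing.assert_allclose(de.log_fc, 0.0, atol=1e-12)

    def test_min_pct_filter_uses_tested_group(self):
        rng = np.random.default_rng(12)
        X1 = rng.uniform(1, 2, size=(2, 40))
        X1[0, 2:] = 0.0  # 5% expressed in group1
        X2 = rng.uniform(1, 2, size=(2, 40))
        m, g1, g2 = self._matrix(X1, X2)
        de = wilcoxon_de(m, g1, g2, min_pct=0.10)
        assert "g0" not in set(de.gene_id)
        assert "g1" in set(de.gene_id)

    def test_bonferroni_over_tested_genes(self):
        rng = np.random.default_rng(13)
        m, g1, g2 = self._matrix(rng.uniform(1, 2, (5, 20)), rng.uniform(1, 2, (5, 20)))
        de = wilcoxon_de(m, g1, g2)
        np.testing.assert_allclose(de.p_adjusted,
                                   np.minimum(1.0, de.p_value * len(de)), atol=1e-12)

    def test_group_overlap_rejected(self):
        m = make_lognorm(np.ones((2, 4)))
        with pytest.raises(ValueError, match="disjoint"):
            wilcoxon_de(m, ["c0", "c1"], ["c1", "c2"])

    def test_tr_genes_recovers_markers_and_skips_empty_strata(self, small_lognorm):
        ln, md, truth = small_lognorm
        labels = pd.Series(truth.cell_subgroup, index=ln.cell_ids, name="subgroup")
        labels[labels == "control"] = np.nan
        res = tr_genes(ln, md, labels)
        for (sg, stim), table in res["tables"].items():
            if sg == "MCI" and table is not None:
                sig_up = table[(table.significant) & (table.direction == "up")]
                assert "IL1B" in set(sig_up.gene_id)
        assert {"IL1B", "IL6", "TNF"} <= set(
            res["shared"].loc[res["shared"].subgroup == "MCI", "gene_id"])


def fisher_oracle(a, b, c, d):
    """Exact one-sided p by Fraction-arithmetic enumeration over tables."""
    r1, r2, c1 = a + b, c + d, a + c

    import math

    def comb(n, k):
        return Fraction(math.factorial(n),
                        math.factorial(k) * math.factorial(n - k))

    denom = comb(r1 + r2, c1)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if k >= a:
            total += comb(r1, k) * comb(r2, c1 - k)
    return float(total / denom)


class TestFisher:
    def test_hand_checked_table(self):
        res = fisher_gwas_enrichment({"g1", "g2", "g3", "g4"},
                                     ["g1", "g2", "g3", "x1"],
                                     ["g4", "x2", "x3", "x4"])
        assert res.p_value == pytest.approx(17 / 70)
        assert res.table.tolist() == [[3, 1], [1, 3]]

    def test_matches_fraction_oracle_totals_to_40(self):
        rng = np.random.default_rng(14)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if a + b == 0 or c + d == 0:
                continue
            p = hypergeom_sf_logspace(a, a + b, c + d, a + c)
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-10)

    def test_matches_scipy_one_sided(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 12, 4))
            p = hypergeom_sf_logspace(a, a + b, c + d, a + c)
            ref = sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert p == pytest.approx(ref, rel=1e-9)

    def test_degenerate_disjoint_tr_set(self):
        res = fisher_gwas_enrichment({"z1"}, ["a", "b"], ["c", "d"])
        assert res.p_value == 1.0
        assert np.isnan(res.odds_ratio)


class TestGenesNearSnps:
    GENES = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                          "start": [100_000, 1_000_000, 100_000],
                          "end": [200_000, 1_010_000, 200_000],
                          "gene_id": ["gA", "gB", "gC"]})

    def test_coordinate_arithmetic(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [500_000], "snp_id": ["rs1"]})
        assert genes_near_snps(self.GENES, snps, window=250_000) == []
        assert genes_near_snps(self.GENES, snps, window=300_000) == ["gA"]
        assert genes_near_snps(self.GENES, snps, window=500_001) == ["gA", "gB"]

    def test_snp_inside_body_any_window(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [150_000], "snp_id": ["rs1"]})
        for w in (0, 10, 1_000_000):
            assert "gA" in genes_near_snps(self.GENES, snps, window=w)

    def test_window_zero_body_only(self):
        # 1-based pos 200000 is the last body base of [100000, 200000)
        inside = pd.DataFrame({"chrom": ["chr1"], "pos": [200_000], "snp_id": ["r1"]})
        outside = pd.DataFrame({"chrom": ["chr1"], "pos": [200_001], "snp_id": ["r2"]})
        assert genes_near_snps(self.GENES, inside, window=0) == ["gA"]
        assert genes_near_snps(self.GENES, outside, window=0) == []

    def test_chromosomes_do_not_mix(self):
        snps = pd.DataFrame({"chrom": ["chr2"], "pos": [150_000], "snp_id": ["rs1"]})
        assert genes_near_snps(self.GENES, snps, window=10_000_000) == ["gC"]


class TestDirichletRegression:
    def test_loglik_matches_scipy_dirichlet(self):
        rng = np.random.default_rng(16)
        Y = rng.dirichlet((2, 3, 4), size=12)
        X = np.ones((12, 1))
        beta = np.log([[2.0, 3.0, 4.0]])
        nll, _ = _dirichlet_nll_grad(beta.ravel(), X, Y, 3)
        ref = sum(sps.dirichlet.logpdf(y, (2, 3, 4)) for y in Y)
        assert -nll == pytest.approx(ref, rel=1e-10)

    def test_intercept_recovery(self):
        tab = simulate_composition(250, (2, 4, 8), (2, 4, 8), seed=17)
        fit = dirichlet_regression(tab, covariates=["group"])
        want = np.array([1, 2, 4]) / 7
        got = fit["fitted_means"].to_numpy()
        assert np.abs(got / want - 1).max() < 0.05
        assert fit["converged"]

    def test_group_shift_detected(self):
        tab = simulate_composition(20, (8, 2, 2), (2, 2, 8), seed=18)
        fit = dirichlet_regression(tab, covariates=["group"])
        assert fit["p_value"] < 1e-6

    def test_mle_beats_generating_parameters(self):
        tab = simulate_composition(30, (2, 4, 8), (2, 4, 8), seed=19)
        fit = dirichlet_regression(tab, covariates=["group"])
        from tisig.stats import _zero_shrink
        Y = _zero_shrink(tab[["MCI", "MC", "NT"]].to_numpy())
        ll_true = sum(sps.dirichlet.logpdf(y, (2, 4, 8)) for y in Y)
        assert fit["log_likelihood"] >= ll_true - 1e-6

    def test_single_component_rejected(self):
        tab = simulate_composition(5, (2, 3, 4), (2, 3, 4), seed=0)
        with pytest.raises(ValueError, match="2 components"):
            dirichlet_regression(tab, components=("MCI",))

    def test_small_factor_level_rejected(self):
        tab = simulate_composition(5, (2, 3, 4), (2, 3, 4), seed=0)
        tab.loc[tab.index[-1], "group"] = "g3"
        with pytest.raises(ValueError, match="at least 2 samples"):
            dirichlet_regression(tab, covariates=["group"])


class TestOverrepresentation:
    UNIVERSE = [f"u{i}" for i in range(40)]

    def test_set_equal_universe_p_one(self):
        sets = [GeneSignature("all", tuple(self.UNIVERSE))]
        out = overrepresentation_gmt(self.UNIVERSE[:5], sets, self.UNIVERSE)
        assert out.p_value.iloc[0] == pytest.approx(1.0)

    def test_bh_adjustment_matches_step_up_oracle(self):
        def bh_oracle(ps):
            m = len(ps)
            order = np.argsort(ps)
            adj = np.empty(m)
            running = 1.0
            for rank_from_top, idx in enumerate(reversed(order)):
                rank = m - rank_from_top
                running = min(running, ps[idx] * m / rank)
                adj[idx] = running
            return adj

        rng = np.random.default_rng(21)
        sets = [GeneSignature(f"s{i}",
                              tuple(rng.choice(self.UNIVERSE, int(rng.integers(3, 12)),
                                               replace=False)))
                for i in range(8)]
        out = overrepresentation_gmt(list(self.UNIVERSE[:12]), sets, self.UNIVERSE)
        np.testing.assert_allclose(out.p_adjusted, bh_oracle(out.p_value.to_numpy()),
                                   atol=1e-12)

    def test_adjusted_never_below_raw_and_expected_nonnegative(self):
        rng = np.random.default_rng(20)
        sets = [GeneSignature(f"s{i}", tuple(rng.choice(self.UNIVERSE, 8, replace=False)))
                for i in range(6)]
        out = overrepresentation_gmt(list(self.UNIVERSE[:10]), sets, self.UNIVERSE)
        assert (out.p_adjusted >= out.p_value - 1e-12).all()
        assert (out.expected >= 0).all()

    def test_gene_list_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            overrepresentation_gmt(["nope"], [], self.UNIVERSE)
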