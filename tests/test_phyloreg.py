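"""Unit tests for tree handling, PGLS, FDR, clade scans, and overlap tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from mucocosm import phyloreg, simulate
from conftest import brute_force_gls


class TestParseNewick:
    def test_hand_depths(self, hand_tree):
        C = phyloreg.bm_covariance(hand_tree, ["A", "B", "C"])
        assert np.allclose(np.diag(C), [2, 2, 2])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            phyloreg.parse_newick("(A:1,A:1,B:1);")

    def test_polytomy_accepted(self):
        tree = phyloreg.parse_newick("(A:1,B:1,C:1);")
        assert sorted(phyloreg.leaf_labels(tree)) == ["A", "B", "C"]

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            phyloreg.parse_newick("((A:1,B):1,C:2);")

    def test_unbalanced_rejected(self):
        with pytest.raises(Exception):
            phyloreg.parse_newick("((A:1,B:1:1,C:2);")


class TestBMCovariance:
    def test_hand_values(self, hand_tree):
        C = phyloreg.bm_covariance(hand_tree, ["A", "B", "C"]).to_numpy()
        assert np.allclose(C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_is_identity(self, star_tree_factory):
        tree, labels = star_tree_factory(5)
        C = phyloreg.bm_covariance(tree, labels).to_numpy()
        assert np.allclose(C, np.eye(5))

    def test_positive_semidefinite(self):
        for seed in range(5):
            tree = simulate.simulate_tree(20, seed)
            C = phyloreg.bm_covariance(tree, phyloreg.leaf_labels(tree))
            assert np.linalg.eigvalsh(C.to_numpy()).min() >= -1e-10

    def test_shared_path_bounded_by_depths(self):
        tree = simulate.simulate_tree(12, 3)
        C = phyloreg.bm_covariance(tree, phyloreg.leaf_labels(tree)).to_numpy()
        d = np.diag(C)
        assert (C <= np.minimum.outer(d, d) + 1e-12).all()

    def test_unknown_strain_listed(self, hand_tree):
        with pytest.raises(KeyError, match="Z"):
            phyloreg.bm_covariance(hand_tree, ["A", "Z"])


class TestPGLS:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        fit = phyloreg.pgls_fit(y, x, np.eye(10))
        ols = stats.linregress(x, y)
        assert fit.beta == pytest.approx(ols.slope, abs=1e-10)
        assert fit.se == pytest.approx(ols.stderr, abs=1e-10)
        assert fit.p == pytest.approx(ols.pvalue, abs=1e-10)

    def test_perfect_fit(self, hand_tree):
        C = phyloreg.bm_covariance(hand_tree, ["A", "B", "C"])
        x = np.array([0.0, 1.0, 2.0])
        fit = phyloreg.pgls_fit(2 * x, x, C)
        assert fit.beta == pytest.approx(2.0)
        assert fit.p == 0.0

    def test_matches_brute_force_gls(self):
        rng = np.random.default_rng(7)
        tree = simulate.simulate_tree(9, 2)
        C = phyloreg.bm_covariance(tree, phyloreg.leaf_labels(tree)).to_numpy()
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        fit = phyloreg.pgls_fit(y, x, C)
        b, se, p = brute_force_gls(y, x, C)
        assert fit.beta == pytest.approx(b, abs=1e-10)
        assert fit.se == pytest.approx(se, abs=1e-10)
        assert fit.p == pytest.approx(p, abs=1e-10)

    def test_invariant_to_covariance_scale(self):
        rng = np.random.default_rng(3)
        tree = simulate.simulate_tree(8, 5)
        C = phyloreg.bm_covariance(tree, phyloreg.leaf_labels(tree)).to_numpy()
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        a = phyloreg.pgls_fit(y, x, C)
        b = phyloreg.pgls_fit(y, x, 37.5 * C)
        assert a.beta == pytest.approx(b.beta, abs=1e-10)
        assert a.t == pytest.approx(b.t, abs=1e-10)
        assert a.p == pytest.approx(b.p, abs=1e-10)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="3"):
            phyloreg.pgls_fit([1, 2], [0, 1], np.eye(2))

    def test_constant_regressor(self):
        with pytest.raises(ValueError, match="variance"):
            phyloreg.pgls_fit([1.0, 2.0, 3.0], [1, 1, 1], np.eye(3))


class TestBHFDR:
    def test_hand_stepup(self):
        q = phyloreg.bh_fdr([0.001, 0.02, 0.9])
        assert np.allclose(q, [0.003, 0.03, 0.9])

    def test_all_ones(self):
        assert np.allclose(phyloreg.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert phyloreg.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            phyloreg.bh_fdr([0.1, 1.2])

    def test_uniform_null_controls_discoveries(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=5000)
        assert (phyloreg.bh_fdr(p) < 0.01).mean() <= 0.01


class TestAssociationScan:
    def test_constant_columns_untested(self):
        tree = simulate.simulate_tree(6, 1)
        strains = phyloreg.leaf_labels(tree)
        G = pd.DataFrame({"k1": np.ones(6), "k2": np.full(6, 3.0)},
                         index=strains)
        y = pd.Series(np.arange(6, dtype=float), index=strains)
        scan = phyloreg.association_scan(G, y, tree)
        assert not scan["tested"].any()
        assert not scan["significant"].any()

    def test_scan_column_matches_pgls_fit(self):
        tree = simulate.simulate_tree(20, 4)
        g = simulate.simulate_genotypes(tree, 5, 0.5, 4)
        y = simulate.simulate_phenotype(tree, g, [], 0.0, 1.0, 0.0, 5)
        scan = phyloreg.association_scan(g.bitscores, y, tree)
        strains = phyloreg.leaf_labels(tree)
        C = phyloreg.bm_covariance(tree, strains)
        col = g.bitscores["K00003"]
        z = (col - col.mean()) / col.std(ddof=0)
        fit = phyloreg.pgls_fit(y.loc[strains], z.loc[strains], C)
        assert scan.loc["K00003", "beta"] == pytest.approx(fit.beta, rel=1e-10)
        assert scan.loc["K00003", "p"] == pytest.approx(fit.p, rel=1e-8)

    def test_missing_phenotypes_dropped(self):
        tree = simulate.simulate_tree(10, 2)
        g = simulate.simulate_genotypes(tree, 4, 0.5, 2)
        y = simulate.simulate_phenotype(tree, g, [], 0.0, 1.0, 0.1, 3)
        y.iloc[:2] = np.nan
        scan = phyloreg.association_scan(g.bitscores, y, tree)
        assert (scan["n"] == 8).all()

    def test_too_few_strains_after_dropping(self):
        tree = simulate.simulate_tree(4, 2)
        g = simulate.simulate_genotypes(tree, 2, 0.5, 2)
        y = pd.Series(np.nan, index=g.strains)
        y.iloc[0] = 1.0
        with pytest.raises(ValueError, match=">= 3"):
            phyloreg.association_scan(g.bitscores, y, tree)

    def test_pooled_null_significance_stays_low(self):
        """Planted-effect scans: nulls significant at q<0.01 stay <= 5%,
        pooled over 50 seeded replicates, and the causal KO is recovered."""
        from mucocosm.pipeline import child_seed
        hit, frac = [], []
        for s in range(50):
            tree = simulate.simulate_tree(64, child_seed(s, "tree"))
            g = simulate.simulate_genotypes(tree, 501, 0.5,
                                            child_seed(s, "genotypes"))
            y = simulate.simulate_phenotype(tree, g, ["K00001"], 2.0, 1.0,
                                            0.1, child_seed(s, "phenotype"))
            scan = phyloreg.association_scan(g.bitscores, y, tree, fdr=0.01)
            hit.append(bool(scan.loc["K00001", "significant"]))
            frac.append(scan.drop(index="K00001")["significant"].mean())
        assert sum(hit) >= 48
        assert np.mean(frac) <= 0.05

    def test_phenotype_permutation_breaks_signal(self):
        """Permuting the phenotype across strains destroys the genotype
        linkage: the causal KO loses its preferential significance and is
        discovered no more often than an exchangeable null feature."""
        rng = np.random.default_rng(11)
        tree = simulate.simulate_tree(64, 21)
        g = simulate.simulate_genotypes(tree, 300, 0.5, 22)
        y = simulate.simulate_phenotype(tree, g, ["K00001"], 2.0, 1.0, 0.1, 23)
        unpermuted = phyloreg.association_scan(g.bitscores, y, tree, fdr=0.01)
        assert bool(unpermuted.loc["K00001", "significant"])
        causal_sig = 0
        for _ in range(10):
            perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            scan = phyloreg.association_scan(g.bitscores, perm, tree,
                                             fdr=0.01)
            causal_sig += bool(scan.loc["K00001", "significant"])
        assert causal_sig <= 3


class TestCladeScan:
    def test_single_phylum_equals_global(self):
        tree = simulate.simulate_tree(10, 6)
        g = simulate.simulate_genotypes(tree, 20, 0.5, 6)
        y = simulate.simulate_phenotype(tree, g, [], 0.0, 1.0, 0.1, 7)
        tax = pd.Series("Bacteroidota", index=g.strains)
        res = phyloreg.clade_scan(g.bitscores, y, tree, tax)
        glob = phyloreg.association_scan(g.bitscores, y, tree)
        assert list(res) == ["Bacteroidota"]
        pd.testing.assert_frame_equal(res["Bacteroidota"], glob)

    def test_firmicutes_lineages_merge(self):
        tree = simulate.simulate_tree(12, 8)
        g = simulate.simulate_genotypes(tree, 10, 0.5, 8)
        y = simulate.simulate_phenotype(tree, g, [], 0.0, 1.0, 0.1, 9)
        strains = g.strains
        labels = (["Firmicutes", "Firmicutes_A", "Firmicutes_C"] * 4)[:12]
        tax = pd.Series(labels, index=strains)
        res = phyloreg.clade_scan(g.bitscores, y, tree, tax)
        assert list(res) == ["Firmicutes_merged"]
        assert (res["Firmicutes_merged"]["n"] == 12).all()

    def test_small_clades_skipped(self):
        tree = simulate.simulate_tree(10, 3)
        g = simulate.simulate_genotypes(tree, 10, 0.5, 3)
        y = simulate.simulate_phenotype(tree, g, [], 0.0, 1.0, 0.1, 4)
        tax = pd.Series(["Big"] * 8 + ["Tiny"] * 2, index=g.strains)
        res = phyloreg.clade_scan(g.bitscores, y, tree, tax)
        assert "Tiny" not in res and "Big" in res

    def test_planted_clade_specific_effect_detected(self):
        """An effect present only inside one clade is found there and not in
        the other clade, across seeds."""
        found_in, found_out, evaluated, seed = 0, 0, 0, 0
        while evaluated < 5 and seed < 30:
            seed += 1
            tree = simulate.simulate_tree(40, 100 + seed)
            g = simulate.simulate_genotypes(tree, 100, 0.5, 200 + seed)
            tax = simulate.clade_labels(tree, 2)
            clades = sorted(tax.unique())
            if len(clades) < 2:
                continue
            members = tax[tax == clades[0]].index
            if len(members) < 10 or len(tax) - len(members) < 10:
                continue
            col = g.presence()["K00001"].astype(float)
            zin = col.loc[members]
            if zin.std() == 0:
                continue
            evaluated += 1
            y = simulate.simulate_phenotype(tree, g, [], 0.0, 1.0, 0.1,
                                            300 + seed)
            y.loc[members] += 3.0 * (zin - zin.mean()) / zin.std()
            res = phyloreg.clade_scan(g.bitscores, y, tree, tax, fdr=0.01)
            found_in += bool(res[clades[0]].loc["K00001", "significant"])
            found_out += bool(res[clades[1]].loc["K00001", "significant"])
        assert evaluated == 5
        assert found_in >= 4
        assert found_out <= 1


class TestOverlap:
    def test_symmetric_table(self):
        uni = [f"k{i}" for i in range(40)]
        res = phyloreg.overlap_test(uni[:20], uni[10:30], uni)
        assert res.table == ((10, 10), (10, 10))
        assert res.log_odds == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_nested_lists_capped(self):
        uni = [f"k{i}" for i in range(20)]
        res = phyloreg.overlap_test(uni[:10], uni[:10], uni)
        assert res.capped
        assert res.log_odds > 0
        assert res.p < 1e-4

    def test_hand_table_matches_hypergeometric_enumeration(self):
        # universe of 20, A = first 10, B chosen so the table is [[8,2],[1,9]]
        uni = [f"k{i}" for i in range(20)]
        A = uni[:10]
        B = uni[:8] + [uni[10]]
        res = phyloreg.overlap_test(A, B, uni)
        assert res.table == ((8, 2), (1, 9))
        # exhaustive two-sided Fisher p over tables with fixed margins
        n, r, c = 20, 10, 9  # total, |A|, |B|
        probs = {}
        for a in range(max(0, r + c - n), min(r, c) + 1):
            probs[a] = (comb(r, a) * comb(n - r, c - a)) / comb(n, c)
        p_obs = probs[8]
        p_two = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
        assert res.p == pytest.approx(p_two, rel=1e-8)
        assert res.ci95[0] < res.log_odds < res.ci95[1]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            phyloreg.overlap_test([], [], [])
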