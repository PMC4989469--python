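"""Mixed-model and threshold-model samplers: degeneracies, determinism,
and recovery on synthetic data."""

import numpy as np
import pytest

from ploidyshift import (
    SimConfig,
    p_mcmc,
    phylo_covariance,
    phylo_lmm,
    simulate_bd_tree,
    simulate_phylo_gaussian,
    simulate_threshold_traits,
    taxonomic_lmm,
    threshold_model,
)
from ploidyshift.synthetic_data import assign_taxonomy, make_trait_table
import pandas as pd


class TestPMcmc:
    def test_all_positive_hits_floor(self):
        assert p_mcmc(np.ones(500)) == pytest.approx(2 / 500)

    def test_symmetric_samples_near_one(self):
        s = np.concatenate([np.ones(300), -np.ones(300)])
        assert p_mcmc(s) == pytest.approx(1.0)

    def test_direct_computation(self):
        s = np.array([-1.0] * 75 + [1.0] * 25)
        assert p_mcmc(s) == pytest.approx(0.5)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            p_mcmc(np.ones(10))


class TestPhyloCovariance:
    def test_shared_path_lengths(self):
        from ploidyshift import TimeTree

        t = TimeTree.from_newick("((A:1,B:1):1,C:2);")
        C = phylo_covariance(t, normalize=False)
        a, b, c = t.tip_index("A"), t.tip_index("B"), t.tip_index("C")
        assert C[a, a] == pytest.approx(2.0)
        assert C[a, b] == pytest.approx(1.0)
        assert C[a, c] == pytest.approx(0.0)
        Cn = phylo_covariance(t)
        assert Cn[a, a] == pytest.approx(1.0)


class TestPhyloLmm:
    def test_beta_recovery_and_heritability(self):
        tree = simulate_bd_tree(SimConfig(n_tips=100, seed=1))
        rng = np.random.default_rng(2)
        z = (rng.random(100) < 0.3).astype(float)
        y = simulate_phylo_gaussian(tree, z, beta=-0.3, sigma2_phylo=0.09,
                                    sigma2_resid=0.01, seed=3)
        res = phylo_lmm(tree, y, z, n_iter=3000, burnin=800, thin=2, seed=4)
        assert res.beta_ci[0] < -0.3 < res.beta_ci[1]
        assert 0.7 < res.heritability_mean <= 1.0
        assert res.p_mcmc < 0.05
        assert np.all((res.samples["heritability"] >= 0) & (res.samples["heritability"] <= 1))

    def test_shuffled_ploidy_not_significant(self):
        tree = simulate_bd_tree(SimConfig(n_tips=80, seed=5))
        rng = np.random.default_rng(6)
        z = (rng.random(80) < 0.3).astype(float)
        y = simulate_phylo_gaussian(tree, np.zeros(80), beta=0.0, sigma2_phylo=0.05,
                                    sigma2_resid=0.01, seed=7)
        res = phylo_lmm(tree, y, z, n_iter=2500, burnin=600, thin=2, seed=8)
        assert res.beta_ci[0] < 0 < res.beta_ci[1]

    def test_star_tree_matches_ols(self):
        """On a star phylogeny with a dominant residual component the fixed
        effect collapses to the ordinary least-squares group contrast."""
        from ploidyshift import TimeTree

        n = 60
        nwk = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        tree = TimeTree.from_newick(nwk)
        rng = np.random.default_rng(9)
        z = (np.arange(n) % 2).astype(float)
        y = 3.0 - 0.4 * z + rng.normal(0, 0.1, n)
        res = phylo_lmm(tree, y, z, n_iter=2500, burnin=600, thin=2, seed=10)
        ols = y[z == 1].mean() - y[z == 0].mean()
        assert res.beta_mean == pytest.approx(ols, abs=0.05)

    def test_seed_determinism(self):
        tree = simulate_bd_tree(SimConfig(n_tips=40, seed=11))
        z = (np.arange(40) % 2).astype(float)
        y = simulate_phylo_gaussian(tree, z, -0.2, 0.05, 0.01, seed=12)
        r1 = phylo_lmm(tree, y, z, n_iter=800, burnin=200, thin=2, seed=13)
        r2 = phylo_lmm(tree, y, z, n_iter=800, burnin=200, thin=2, seed=13)
        assert r1.samples.equals(r2.samples)

    def test_tree_set_pooling(self):
        trees = [simulate_bd_tree(SimConfig(n_tips=40, seed=s)) for s in (14, 15)]
        z = (np.arange(40) % 2).astype(float)
        y = simulate_phylo_gaussian(trees[0], z, -0.2, 0.05, 0.01, seed=16)
        res = phylo_lmm(trees, y, z, n_iter=600, burnin=200, thin=2, seed=17)
        assert res.diagnostics["n_trees"] == 2
        assert res.diagnostics["n_samples"] == 2 * 200


class TestTaxonomicLmm:
    def _table(self, tree, systems, counts):
        recs = make_trait_table(tree, systems, counts, assign_taxonomy(tree))
        return pd.DataFrame([vars(r) for r in recs])

    def test_group_difference_recovered(self):
        tree = simulate_bd_tree(SimConfig(n_tips=100, seed=18))
        rng = np.random.default_rng(19)
        systems = (rng.random(100) < 0.35).astype(int)
        y = 2.9 - 0.3 * systems + rng.normal(0, 0.15, 100)
        counts = np.rint(np.exp(y)).astype(int)
        df = self._table(tree, systems, counts)
        res = taxonomic_lmm(df, n_iter=3000, burnin=800, thin=2, seed=20)
        assert res.beta_ci[0] < res.beta_mean < res.beta_ci[1]
        assert res.beta_mean < -0.1
        assert res.p_mcmc < 0.05

    def test_sign_agreement_with_phylo_lmm(self):
        tree = simulate_bd_tree(SimConfig(n_tips=100, seed=21))
        rng = np.random.default_rng(22)
        systems = (rng.random(100) < 0.3).astype(int)
        y = simulate_phylo_gaussian(tree, systems.astype(float), beta=-0.35,
                                    sigma2_phylo=0.05, sigma2_resid=0.02, seed=23)
        counts = np.rint(np.exp(y)).astype(int)
        df = self._table(tree, systems, counts)
        res_t = taxonomic_lmm(df, n_iter=2500, burnin=600, thin=2, seed=24)
        res_p = phylo_lmm(tree, np.log(counts.astype(float)), systems.astype(float),
                          n_iter=2500, burnin=600, thin=2, seed=25)
        assert res_t.beta_mean < 0 and res_p.beta_mean < 0
        assert abs(res_t.beta_mean - res_p.beta_mean) < 0.25

    def test_singleton_level_dropped_with_warning(self):
        tree = simulate_bd_tree(SimConfig(n_tips=30, seed=26))
        rng = np.random.default_rng(27)
        systems = (rng.random(30) < 0.4).astype(int)
        counts = rng.integers(10, 30, 30)
        df = self._table(tree, systems, counts)
        df["genus"] = [f"G{i}" for i in range(30)]  # all singletons
        with pytest.warns(UserWarning, match="singleton"):
            res = taxonomic_lmm(df, n_iter=500, burnin=100, thin=2, seed=28)
        assert "v_genus" not in res.samples.columns


class TestThreshold:
    def test_recovery_of_negative_liability_correlation(self):
        tree = simulate_bd_tree(SimConfig(n_tips=100, seed=29))
        ploidy, y = simulate_threshold_traits(tree, corr=-0.8, seed=30)
        res = threshold_model(tree, y, ploidy, n_iter=2000, burnin=500, thin=2, seed=31)
        assert -1.0 <= res.corr_mean <= 1.0
        assert abs(res.corr_mean - (-0.8)) < 0.25
        assert res.corr_ci[0] < res.corr_mean < res.corr_ci[1]

    def test_independent_traits_ci_covers_zero(self):
        tree = simulate_bd_tree(SimConfig(n_tips=80, seed=32))
        ploidy, _ = simulate_threshold_traits(tree, corr=0.0, seed=33)
        _, y = simulate_threshold_traits(tree, corr=0.0, seed=34)
        res = threshold_model(tree, y, ploidy, n_iter=1500, burnin=400, thin=2, seed=35)
        assert res.corr_ci[0] < 0 < res.corr_ci[1]

    def test_deterministic_dichotomisation_gives_extreme_r(self):
        tree = simulate_bd_tree(SimConfig(n_tips=100, seed=36))
        _, y = simulate_threshold_traits(tree, corr=0.0, seed=37)
        ploidy = (y < np.median(y)).astype(int)  # ploidy determined by 2n
        res = threshold_model(tree, y, ploidy, n_iter=1500, burnin=400, thin=2, seed=38)
        assert res.corr_mean < -0.8

    def test_seed_determinism(self):
        tree = simulate_bd_tree(SimConfig(n_tips=40, seed=39))
        ploidy, y = simulate_threshold_traits(tree, corr=-0.5, seed=40)
        r1 = threshold_model(tree, y, ploidy, n_iter=400, burnin=100, seed=41)
        r2 = threshold_model(tree, y, ploidy, n_iter=400, burnin=100, seed=41)
        assert r1.samples.equals(r2.samples)
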