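"""Stochastic character maps: posteriors, bridges, and origin counts."""

import math

import numpy as np
import pytest

from ploidyshift import (
    MkRates,
    SimConfig,
    TimeTree,
    count_origins,
    marginal_node_posteriors,
    sample_history,
    simulate_bd_tree,
    simulate_joint_traits,
    simulate_mk_tips,
    summarize_origins,
)
from ploidyshift.stochastic_mapping import SimmapHistory, _sample_branch_path

from conftest import brute_force_loglik, fitch_count, random_tree


class TestMarginalPosteriors:
    def test_all_D_tiny_rates(self):
        t = random_tree(8, seed=0)
        post = marginal_node_posteriors(t, np.zeros(8, dtype=int), MkRates(1e-8, 0.0), "fixed_D")
        assert np.allclose(post[:, 0], 1.0, atol=1e-5)

    def test_matches_enumeration_on_three_tip_tree(self):
        t = TimeTree.from_newick("((A:0.6,B:1.1):0.4,C:1.3);")
        states = np.array([0, 1, 0])
        q01, q10 = 0.7, 0.4
        post = marginal_node_posteriors(t, states, MkRates(q01, q10), "stationary")
        # Bayes' theorem by enumeration: P(node = s | data) via clamping
        for v in range(t.n_tips, t.n_nodes):
            tot = brute_force_loglik(t, states, q01, q10, "stationary")
            import itertools

            from conftest import expm_transition

            prior = np.array([q10, q01]) / (q01 + q10)
            P = {u: expm_transition(q01, q10, float(t.blen[u])) for u in range(t.n_nodes)}
            num = np.zeros(2)
            internals = list(range(t.n_tips, t.n_nodes))
            for assign in itertools.product((0, 1), repeat=len(internals)):
                s = {i: int(states[i]) for i in range(t.n_tips)}
                s.update(zip(internals, assign))
                p = prior[s[t.root]]
                for u in range(t.n_nodes):
                    if u != t.root:
                        p *= P[u][s[int(t.parent[u])], s[u]]
                num[s[v]] += p
            want = num / num.sum()
            assert np.allclose(post[v], want, atol=1e-12)
            assert post[v].sum() == pytest.approx(1.0)

    def test_symmetric_cherry_gives_half_half_root(self):
        t = TimeTree.from_newick("(A:1,B:1);")
        post = marginal_node_posteriors(t, np.array([0, 1]), MkRates(0.5, 0.5), "stationary")
        assert np.allclose(post[t.root], [0.5, 0.5], atol=1e-12)


class TestSampleHistory:
    def test_all_D_tiny_rates_empty_history(self):
        t = random_tree(10, seed=1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            h = sample_history(t, np.zeros(10, dtype=int), MkRates(1e-6, 0.0), "fixed_D", rng)
            assert count_origins(h) == 0

    def test_irreversible_history_has_an_origin_per_H_clade(self):
        t = random_tree(30, seed=2)
        st = simulate_mk_tips(t, 0.1, 0.0, seed=3)
        if st.sum() == 0:
            pytest.skip("no haplodiploid tips in draw")
        fitq = MkRates(0.1, 0.0)
        rng = np.random.default_rng(4)
        for _ in range(10):
            h = sample_history(t, st, fitq, "fixed_D", rng)
            h.validate(st)
            assert count_origins(h) >= 1
            assert count_origins(h) >= fitch_count(t, st)

    def test_seed_determinism(self):
        t = random_tree(15, seed=5)
        st = simulate_mk_tips(t, 0.2, 0.1, seed=6)
        h1 = sample_history(t, st, MkRates(0.2, 0.1), "stationary", seed=77)
        h2 = sample_history(t, st, MkRates(0.2, 0.1), "stationary", seed=77)
        assert h1.root_state == h2.root_state
        assert h1.events == h2.events

    def test_root_state_frequency_matches_marginal(self):
        t = TimeTree.from_newick("(((A:0.5,B:0.5):0.5,C:1.0):0.5,(D:0.7,E:0.7):0.8);")
        st = np.array([0, 1, 0, 1, 0])
        rates = MkRates(0.8, 0.5)
        post = marginal_node_posteriors(t, st, rates, "stationary")
        rng = np.random.default_rng(8)
        n = 4000
        hits = sum(
            sample_history(t, st, rates, "stationary", rng).root_state == 0 for _ in range(n)
        )
        p = post[t.root, 0]
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se + 1e-9

    def test_impossible_endpoints_error(self):
        with pytest.raises(ValueError):
            _sample_branch_path(np.random.default_rng(0), 1, 0, 1.0, MkRates(0.5, 0.0))


class TestBranchBridges:
    @pytest.mark.parametrize(
        "q01,q10,t,i", [(0.5, 0.3, 1.2, 0), (2.0, 0.1, 0.8, 1), (0.05, 0.05, 3.0, 0)]
    )
    def test_bridge_endpoint_marginals(self, q01, q10, t, i):
        """Endpoint-conditioned paths, marginalised over the sampled end
        state, must reproduce the analytic transition probabilities."""
        from ploidyshift import binary_transition_matrix

        rates = MkRates(q01, q10)
        rng = np.random.default_rng(123)
        P = binary_transition_matrix(rates, t)
        n = 3000
        for j in (0, 1):
            if P[i, j] < 1e-3:
                continue
            for _ in range(50):
                ev = _sample_branch_path(rng, i, j, t, rates)
                state = i
                prev = 0.0
                for tt, s in ev:
                    assert prev < tt <= t
                    assert s != state
                    state, prev = s, tt
                assert state == j

    def test_uniformization_agrees_with_rejection(self):
        """Number-of-events distribution from the uniformization fallback
        matches plain rejection sampling on the same bridge."""
        from ploidyshift.stochastic_mapping import _uniformization_bridge

        rates = MkRates(0.9, 0.6)
        i, j, t = 0, 1, 1.5
        rng = np.random.default_rng(9)
        n = 4000
        rej = np.array([len(_sample_branch_path(rng, i, j, t, rates)) for _ in range(n)])
        uni = np.array([len(_uniformization_bridge(rng, i, j, t, (0.9, 0.6))) for _ in range(n)])
        assert abs(rej.mean() - uni.mean()) < 4 * rej.std() / math.sqrt(n) + 0.05
        assert abs((rej == 1).mean() - (uni == 1).mean()) < 0.05


class TestOriginCounts:
    def test_empty_history_zero(self):
        t = random_tree(5, seed=10)
        h = SimmapHistory(t, 0, [[] for _ in range(t.n_nodes)], np.zeros(t.n_nodes, dtype=int))
        assert count_origins(h) == 0

    def test_hand_painted_history(self):
        t = TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ns = np.zeros(t.n_nodes, dtype=int)
        ev = [[] for _ in range(t.n_nodes)]
        a, b = t.tip_index("A"), t.tip_index("C")
        ev[a] = [(0.3, 1), (0.8, 0)]  # origin then reversal on A's branch
        ev[b] = [(0.5, 1)]  # origin on C's branch
        ns[b] = 1
        h = SimmapHistory(t, 0, ev, ns)
        assert count_origins(h) == 2

    def test_haplodiploid_root_counts_once(self):
        t = random_tree(5, seed=11)
        h = SimmapHistory(t, 1, [[] for _ in range(t.n_nodes)], np.ones(t.n_nodes, dtype=int))
        assert count_origins(h) == 1

    def test_generator_ground_truth_roundtrip(self):
        cfg = SimConfig(n_tips=60, seed=42)
        tree = simulate_bd_tree(cfg)
        sim = simulate_joint_traits(tree, cfg)
        assert count_origins(sim.history) == sim.n_origins


class TestSummaries:
    def test_single_map_deterministic(self):
        t = random_tree(20, seed=12)
        st = simulate_mk_tips(t, 0.15, 0.0, seed=13)
        if len(np.unique(st)) < 2:
            pytest.skip("monomorphic draw")
        sys_map = dict(zip(t.tip_labels, st))
        s1 = summarize_origins([t], sys_map, "one_rate", n_maps=1, seed=5)
        s2 = summarize_origins([t], sys_map, "one_rate", n_maps=1, seed=5)
        assert s1.counts.tolist() == s2.counts.tolist()
        assert s1.counts.shape == (1, 1)

    def test_model_insensitivity_on_reversion_free_data(self):
        t = random_tree(80, seed=14)
        st = simulate_mk_tips(t, 0.06, 0.0, seed=15)
        if not 0 < st.sum() < 80:
            pytest.skip("degenerate draw")
        sys_map = dict(zip(t.tip_labels, st))
        s1 = summarize_origins([t], sys_map, "one_rate", n_maps=60, seed=1)
        s2 = summarize_origins([t], sys_map, "two_rate", n_maps=60, seed=1)
        se = s1.sd / math.sqrt(60) + s2.sd / math.sqrt(60)
        assert abs(s1.mean - s2.mean) < 3 * se + 1.0
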