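"""Tree I/O, pruning, phylogenetic correlation, Mk likelihood and mapping."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from mimodiv.simulate import simulate_discrete_trait, simulate_ou_traits
from mimodiv.niche import OUParams
from mimodiv.trees import (
    MkParams,
    TraitTable,
    ancestral_marginals,
    fit_mk_ard,
    mk_loglik,
    mk_transition_matrix,
    phylo_correlation,
    prune_tips,
    read_newick,
    stochastic_maps,
)
from tests.conftest import neutral_tree


class TestReadNewick:
    def test_trivial_ultrametric(self, three_tip):
        assert three_tip.tip_labels == ["A", "B", "C"]
        assert three_tip.root_age == pytest.approx(2.0)
        assert three_tip.is_ultrametric()

    def test_non_ultrametric_flagged(self):
        with pytest.warns(UserWarning, match="not ultrametric"):
            t = read_newick("((A:1,B:2):1,C:2);")
        assert not t.is_ultrametric()

    def test_malformed_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            read_newick("((A:1,B:1:1,C:2);")

    def test_missing_branch_length_raises(self):
        with pytest.raises(ValueError, match="branch length"):
            read_newick("((A:1,B),C:2);")

    def test_newick_round_trip(self, three_tip):
        again = read_newick(three_tip.to_newick())
        assert sorted(again.tip_labels) == sorted(three_tip.tip_labels)
        order = [again.tip_labels.index(l) for l in three_tip.tip_labels]
        np.testing.assert_allclose(
            again.patristic_distances()[np.ix_(order, order)],
            three_tip.patristic_distances(),
        )


class TestPrune:
    def test_drop_one_preserves_depths(self, three_tip):
        t = prune_tips(three_tip, ["C"])
        assert t.tip_labels == ["A", "B"]
        np.testing.assert_allclose(t.node_depth[:2], [2.0, 2.0])

    def test_drop_none_identity(self, three_tip):
        t = prune_tips(three_tip, [])
        assert t.to_newick() == three_tip.to_newick()

    def test_drop_all_raises(self, three_tip):
        with pytest.raises(ValueError):
            prune_tips(three_tip, ["A", "B", "C"])

    def test_unknown_tip_raises(self, three_tip):
        with pytest.raises(KeyError):
            prune_tips(three_tip, ["Z"])

    def test_patristic_distances_preserved(self):
        tree, _, _ = neutral_tree(3, 50)
        rng = np.random.default_rng(1)
        drop = [tree.tip_labels[i] for i in rng.choice(tree.n_tips, 10, replace=False)]
        keep_ix = [i for i, l in enumerate(tree.tip_labels) if l not in set(drop)]
        pruned = prune_tips(tree, drop)
        D_before = tree.patristic_distances()[np.ix_(keep_ix, keep_ix)]
        order = [pruned.tip_labels.index(tree.tip_labels[i]) for i in keep_ix]
        D_after = pruned.patristic_distances()[np.ix_(order, order)]
        np.testing.assert_allclose(D_after, D_before, rtol=0, atol=1e-12)


class TestPhyloCorrelation:
    def test_star_tree_identity(self):
        t = read_newick("(A:1,B:1,C:1);")
        np.testing.assert_allclose(phylo_correlation(t), np.eye(3))

    def test_three_tip_values(self, three_tip):
        C = phylo_correlation(three_tip)
        assert C[0, 1] == pytest.approx(0.5)
        assert C[0, 2] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_non_ultrametric_raises(self):
        with pytest.warns(UserWarning):
            t = read_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            phylo_correlation(t)

    def test_psd_unit_diagonal_on_random_trees(self):
        for seed in (1, 2, 3):
            tree, _, _ = neutral_tree(seed, 30)
            C = phylo_correlation(tree)
            np.testing.assert_allclose(C, C.T)
            np.testing.assert_allclose(np.diag(C), 1.0)
            assert np.linalg.eigvalsh(C).min() >= -1e-10

    def test_matches_bm_simulation_covariance(self):
        """Correlation matrix equals normalized covariance of BM replicates."""
        tree, _, _ = neutral_tree(11, 12)
        _, rmap = simulate_discrete_trait(tree, MkParams(0, 0), seed=0, root_state=0)
        bm = OUParams(sigma2=(1.0, 1.0), alpha=(0.0, 0.0), theta=(0.0, 0.0), root_mean=0.0)
        X = simulate_ou_traits(tree, rmap, bm, seed=5, n_rep=40_000)
        emp = np.cov(X.T) / tree.root_age
        np.testing.assert_allclose(emp, phylo_correlation(tree), atol=0.05)


def _enumeration_loglik(tree, states, q, pi):
    """Exhaustive sum over all interior-state assignments (small trees)."""
    interior = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    total = 0.0
    P = {v: mk_transition_matrix(q, tree.edge_length[v]) for v in range(tree.n_nodes)}
    for assign in itertools.product([0, 1], repeat=len(interior)):
        st = {v: s for v, s in zip(interior, assign)}
        st.update({i: int(states[i]) for i in range(tree.n_tips)})
        p = pi[st[tree.root]]
        for v in range(tree.n_nodes):
            if v != tree.root:
                p *= P[v][st[tree.parent[v]], st[v]]
        total += p
    return np.log(total)


class TestMkLoglik:
    def test_zero_rates_flat_prior(self, three_tip):
        ll = mk_loglik(three_tip, np.array([0, 0, 0]), MkParams(0, 0))
        assert ll == pytest.approx(np.log(0.5))

    def test_two_tip_matrix_exponential_oracle(self):
        t = read_newick("(A:1.5,B:0.7);")
        q = MkParams(0.3, 0.12)
        Q = np.array([[-q.q01, q.q01], [q.q10, -q.q10]])
        brute = sum(
            0.5 * expm(Q * 1.5)[r, 0] * expm(Q * 0.7)[r, 1] for r in range(2)
        )
        assert mk_loglik(t, np.array([0, 1]), q) == pytest.approx(np.log(brute))

    @pytest.mark.parametrize("q01,q10", [(0.3, 0.1), (0.05, 0.8), (1.2, 1.2)])
    def test_enumeration_oracle_five_tips(self, q01, q10):
        t = read_newick("(((A:1,B:1):1,(C:1.5,D:0.5):0.5):1,E:3);")
        states = np.array([0, 1, 1, 0, 1])
        q = MkParams(q01, q10)
        expected = _enumeration_loglik(t, states, q, np.array([0.5, 0.5]))
        assert mk_loglik(t, states, q) == pytest.approx(expected, abs=1e-10)

    def test_stationary_prior(self, three_tip):
        q = MkParams(0.4, 0.1)
        ll = mk_loglik(three_tip, np.array([0, 1, 0]), q, root_prior="stationary")
        expected = _enumeration_loglik(three_tip, np.array([0, 1, 0]), q, q.stationary)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_bad_inputs(self, three_tip):
        with pytest.raises(ValueError):
            MkParams(-0.1, 0.2)
        with pytest.raises(ValueError):
            mk_loglik(three_tip, np.array([0, 2, 0]), MkParams(0.1, 0.1))


class TestFitMk:
    def test_all_one_state_boundary(self, yule_tree_50):
        tree, _ = yule_tree_50
        with pytest.warns(UserWarning, match="one state"):
            q, _ = fit_mk_ard(tree, np.ones(tree.n_tips, dtype=int), seed=0)
        assert q.q10 < 1e-6  # unused direction collapses to the bound

    def test_time_rescaling_equivariance(self):
        tree, _, _ = neutral_tree(21, 60)
        states, _ = simulate_discrete_trait(tree, MkParams(0.15, 0.08), seed=2)
        if states.min() == states.max():
            pytest.skip("degenerate simulation")
        q1, _ = fit_mk_ard(tree, states, seed=0)
        doubled = tree
        doubled.edge_length = tree.edge_length * 2
        q2, _ = fit_mk_ard(doubled, states, seed=0)
        assert q2.q01 == pytest.approx(q1.q01 / 2, rel=1e-3)
        assert q2.q10 == pytest.approx(q1.q10 / 2, rel=1e-3)

    def test_simulation_recovery(self):
        """Rates recovered within 50% relative error in most replicates."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            tree, _, _ = neutral_tree(200 + rep, 300)
            states, _ = simulate_discrete_trait(
                tree, MkParams(0.1, 0.02), seed=rep, root_state=0
            )
            if states.min() == states.max():
                continue
            q, _ = fit_mk_ard(tree, states, seed=rep)
            if abs(q.q01 - 0.1) / 0.1 < 0.5 and abs(q.q10 - 0.02) / 0.02 < 0.5:
                hits += 1
        assert hits >= 0.8 * n_rep


class TestStochasticMaps:
    def test_zero_rates_constant_maps(self, three_tip):
        maps = stochastic_maps(
            three_tip, np.array([0, 0, 0]), MkParams(0, 0), n_maps=5, seed=0
        )
        for m in maps:
            m.validate(three_tip)
            assert m.time_in_state(1) == 0.0
            assert m.n_transitions() == 0

    def test_root_frequency_matches_pruning_posterior(self, three_tip):
        q = MkParams(0.5, 0.2)
        states = np.array([0, 1, 0])
        n_maps = 4000
        maps = stochastic_maps(three_tip, states, q, n_maps=n_maps, seed=3)
        freq1 = np.mean([m.node_state[three_tip.root] for m in maps])
        post = ancestral_marginals(three_tip, states, q)[three_tip.root, 1]
        assert abs(freq1 - post) < max(0.02, 3 * np.sqrt(post * (1 - post) / n_maps))

    def test_transition_count_monotone_in_rate(self, yule_tree_50):
        tree, _ = yule_tree_50
        states, _ = simulate_discrete_trait(tree, MkParams(0.1, 0.1), seed=4)
        means = []
        for q in (0.01, 0.1, 1.0):
            maps = stochastic_maps(
                tree, states, MkParams(q, q), n_maps=30, seed=5
            )
            means.append(np.mean([m.n_transitions() for m in maps]))
        assert means[0] < means[1] < means[2]

    def test_maps_consistent_with_tips(self, three_tip):
        q = MkParams(0.4, 0.3)
        states = np.array([1, 0, 1])
        for m in stochastic_maps(three_tip, states, q, n_maps=20, seed=1):
            m.validate(three_tip)
            np.testing.assert_array_equal(m.node_state[:3], states)


class TestTraitTable:
    def test_habit_coding(self):
        import pandas as pd

        df = pd.DataFrame(
            {"species": ["a", "b", "c", "d"],
             "habit": ["deciduous", "evergreen", "semideciduous", None]}
        )
        tt = TraitTable.from_frame(df)
        np.testing.assert_array_equal(tt.habit[:3], [1.0, 0.0, 0.0])
        assert np.isnan(tt.habit[3])
        assert tt.scored().species == ["a", "b", "c"]

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TraitTable(["a", "a"], np.array([0.0, 1.0]))

    def test_unmatched_tips_reported(self, three_tip):
        tt = TraitTable(["A", "B"], np.array([0.0, 1.0]))
        with pytest.raises(KeyError, match="lack trait data"):
            tt.states_for(three_tip)
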