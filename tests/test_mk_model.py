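"""Mk model tests with independent oracles: matrix-exponential transition
probabilities, brute-force summation over root/ancestral states, and
simulation-based parameter recovery."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from areaevo.io_core import parse_newick
from areaevo.mk_model import (
    AreaModel,
    fit_rate,
    marginal_ancestral,
    prune_loglik,
    transition_prob,
)
from areaevo.synthetic_data import SimConfig, sim_bd_tree, sim_mk_tips
from tests.conftest import random_unit_tree


def brute_force_loglik(tree, tips, model):
    """Sum the joint likelihood over every assignment of states to every node."""
    k, q = model.k, model.q
    nodes = list(tree.preorder())
    internal = [nd for nd in nodes if not nd.is_tip]
    total = 0.0
    tip_nodes = [nd for nd in nodes if nd.is_tip]
    tip_choices = []
    for nd in tip_nodes:
        s = tips[nd.name]
        tip_choices.append(sorted(s) if s else list(range(k)))
    for internal_states in itertools.product(range(k), repeat=len(internal)):
        assign = {nd.name: s for nd, s in zip(internal, internal_states)}
        for tip_states in itertools.product(*tip_choices):
            for nd, s in zip(tip_nodes, tip_states):
                assign[nd.name] = s
            p = 1.0 / k
            for nd in nodes:
                if nd is tree.root:
                    continue
                P = transition_prob(q, k, nd.length)
                p *= P[assign[nd.parent.name], assign[nd.name]]
            total += p
    return math.log(total)


def brute_force_marginal(tree, tips, model, node_name):
    k, q = model.k, model.q
    nodes = list(tree.preorder())
    probs = np.zeros(k)
    tip_nodes = [nd for nd in nodes if nd.is_tip]
    internal = [nd for nd in nodes if not nd.is_tip]
    tip_choices = [
        sorted(tips[nd.name]) if tips[nd.name] else list(range(k)) for nd in tip_nodes
    ]
    for internal_states in itertools.product(range(k), repeat=len(internal)):
        assign = {nd.name: s for nd, s in zip(internal, internal_states)}
        for tip_states in itertools.product(*tip_choices):
            for nd, s in zip(tip_nodes, tip_states):
                assign[nd.name] = s
            p = 1.0 / k
            for nd in nodes:
                if nd is tree.root:
                    continue
                P = transition_prob(q, k, nd.length)
                p *= P[assign[nd.parent.name], assign[nd.name]]
            probs[assign[node_name]] += p
    return probs / probs.sum()


class TestTransitionProb:
    def test_t_zero_identity(self):
        assert np.allclose(transition_prob(0.3, 5, 0.0), np.eye(5))

    def test_t_large_uniform(self):
        P = transition_prob(1.0, 4, 1e6)
        assert np.allclose(P, 0.25)

    def test_rows_sum_to_one(self):
        P = transition_prob(0.07, 9, 3.2)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            transition_prob(0.1, 3, -1.0)

    @pytest.mark.parametrize("q,k,t", [(0.05, 9, 10.0), (0.3, 2, 0.7), (1.5, 4, 0.05)])
    def test_matches_matrix_exponential_oracle(self, q, k, t):
        Q = AreaModel(k=k, q=q).rate_matrix()
        assert np.allclose(transition_prob(q, k, t), expm(Q * t), atol=1e-10)

    def test_closed_form_value(self):
        P = transition_prob(0.05, 9, 10.0)
        assert P[0, 0] == pytest.approx(1 / 9 + (8 / 9) * math.exp(-4.5), abs=1e-12)


class TestPruneLoglik:
    def test_two_tip_brute_force(self):
        tree = parse_newick("(A:0.7,B:1.3);")
        model = AreaModel(k=3, q=0.4)
        tips = {"A": frozenset({0}), "B": frozenset({2})}
        expected = 0.0
        for r in range(3):
            expected += (
                (1 / 3)
                * transition_prob(0.4, 3, 0.7)[r, 0]
                * transition_prob(0.4, 3, 1.3)[r, 2]
            )
        assert prune_loglik(tree, tips, model) == pytest.approx(math.log(expected), abs=1e-12)

    def test_all_states_tip_equals_missing(self, four_tip_tree):
        model = AreaModel(k=3, q=0.3)
        base = {"A": frozenset({0}), "B": frozenset({1}), "C": frozenset({2})}
        ll_all = prune_loglik(four_tip_tree, {**base, "D": frozenset({0, 1, 2})}, model)
        ll_missing = prune_loglik(four_tip_tree, {**base, "D": frozenset()}, model)
        assert ll_all == pytest.approx(ll_missing, abs=1e-12)

    def test_q_to_zero_single_state_limit(self, balanced_unit_tree):
        model = AreaModel(k=7, q=1e-9)
        tips = {t: frozenset({3}) for t in balanced_unit_tree.tip_labels}
        assert prune_loglik(balanced_unit_tree, tips, model) == pytest.approx(
            math.log(1 / 7), abs=1e-6
        )

    def test_missing_tip_contributes_zero(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("(((A:1,B:1):1,C:2):0.5,Z:2.5);")
        model = AreaModel(k=4, q=0.2)
        tips = {"A": frozenset({0}), "B": frozenset({1}), "C": frozenset({0})}
        ll1 = prune_loglik(t1, tips, model)
        ll2 = prune_loglik(t2, {**tips, "Z": frozenset()}, model)
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_invariant_under_child_rotation(self):
        a = parse_newick("((A:1,B:1):1,C:2);")
        b = parse_newick("(C:2,(B:1,A:1):1);")
        model = AreaModel(k=3, q=0.35)
        tips = {"A": frozenset({0}), "B": frozenset({0, 1}), "C": frozenset({2})}
        assert prune_loglik(a, tips, model) == pytest.approx(
            prune_loglik(b, tips, model), abs=1e-12
        )

    def test_missing_tip_entry_errors(self, three_tip_tree):
        with pytest.raises(KeyError, match="absent"):
            prune_loglik(three_tip_tree, {"A": frozenset({0})}, AreaModel(k=2, q=0.1))

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_unit_tree(rng, 4)
        k = 3
        model = AreaModel(k=k, q=float(rng.uniform(0.05, 2.0)))
        tips = {}
        for t in tree.tip_labels:
            r = rng.random()
            if r < 0.15:
                tips[t] = frozenset()
            elif r < 0.4:
                tips[t] = frozenset(rng.choice(k, size=2, replace=False).tolist())
            else:
                tips[t] = frozenset({int(rng.integers(k))})
        got = prune_loglik(tree, tips, model)
        assert got == pytest.approx(brute_force_loglik(tree, tips, model), abs=1e-9)

    def test_deep_tree_no_underflow(self):
        rng = np.random.default_rng(0)
        tree = random_unit_tree(rng, 300)
        res = sim_mk_tips(tree, q=2.0, k=9, seed=1)
        ll = prune_loglik(tree, res.tip_areas, AreaModel(k=9, q=2.0))
        assert np.isfinite(ll)


class TestFitRate:
    def test_local_optimum_sanity(self):
        rng = np.random.default_rng(2)
        tree = random_unit_tree(rng, 80)
        res = sim_mk_tips(tree, q=1.0, k=5, seed=3)
        fit = fit_rate(tree, res.tip_areas, k=5)
        ll = lambda q: prune_loglik(tree, res.tip_areas, AreaModel(k=5, q=q))
        assert fit.loglik >= ll(fit.q_hat * 0.5)
        assert fit.loglik >= ll(fit.q_hat * 2.0)
        assert not fit.at_bound

    def test_all_same_state_hits_lower_bound(self):
        rng = np.random.default_rng(4)
        tree = random_unit_tree(rng, 20)
        tips = {t: frozenset({1}) for t in tree.tip_labels}
        fit = fit_rate(tree, tips, k=3)
        assert fit.at_bound
        assert fit.q_hat < 1e-6

    def test_all_missing_errors(self, balanced_unit_tree):
        tips = {t: frozenset() for t in balanced_unit_tree.tip_labels}
        with pytest.raises(ValueError, match="missing"):
            fit_rate(balanced_unit_tree, tips)

    @pytest.mark.parametrize("q_true", [0.5, 2.0])
    def test_recovery_medium(self, q_true):
        # reduced-scale recovery check (full scale lives in the acceptance suite)
        q_hats = []
        for seed in range(10):
            cfg = SimConfig(n_tips=200, birth_rate=1.0, death_rate=0.0, rng_seed=seed)
            tree, _ = sim_bd_tree(cfg)
            tree = tree.scale(1.0 / tree.root_age)
            res = sim_mk_tips(tree, q=q_true, k=9, seed=seed + 1000)
            q_hats.append(fit_rate(tree, res.tip_areas, k=9).q_hat)
        med = float(np.median(q_hats))
        assert abs(med - q_true) / q_true < 0.2


class TestMarginalAncestral:
    def test_symmetric_two_tip_root(self):
        tree = parse_newick("(A:1,B:1);")
        model = AreaModel(k=2, q=0.3)
        tips = {"A": frozenset({0}), "B": frozenset({1})}
        marg = marginal_ancestral(tree, tips, model)
        assert marg[tree.root.name] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_vectors_sum_to_one(self, four_tip_tree):
        model = AreaModel(k=4, q=0.2)
        tips = {
            "A": frozenset({0}), "B": frozenset({1}),
            "C": frozenset({2, 3}), "D": frozenset(),
        }
        marg = marginal_ancestral(four_tip_tree, tips, model)
        for v in marg.values():
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
            assert (v >= 0).all()

    def test_single_state_tip_probability_one(self, four_tip_tree):
        model = AreaModel(k=3, q=0.4)
        tips = {
            "A": frozenset({0}), "B": frozenset({1}),
            "C": frozenset({2}), "D": frozenset({1}),
        }
        marg = marginal_ancestral(four_tip_tree, tips, model)
        assert marg["A"][0] == pytest.approx(1.0, abs=1e-12)
        assert marg["D"][1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_unit_tree(rng, 4)
        k = 3
        model = AreaModel(k=k, q=float(rng.uniform(0.1, 1.5)))
        tips = {t: frozenset({int(rng.integers(k))}) for t in tree.tip_labels}
        tips[tree.tip_labels[0]] = frozenset({0, 1})
        marg = marginal_ancestral(tree, tips, model)
        for nd in tree.preorder():
            if nd.is_tip:
                continue
            oracle = brute_force_marginal(tree, tips, model, nd.name)
            assert marg[nd.name] == pytest.approx(oracle, abs=1e-9)

    def test_polytomy_handled(self):
        tree = parse_newick("(A:1,B:1,C:1,(D:0.5,E:0.5):0.5);")
        model = AreaModel(k=3, q=0.3)
        tips = {
            "A": frozenset({0}), "B": frozenset({0}), "C": frozenset({1}),
            "D": frozenset({2}), "E": frozenset({2}),
        }
        marg = marginal_ancestral(tree, tips, model)
        oracle = brute_force_marginal(tree, tips, model, tree.root.name)
        assert marg[tree.root.name] == pytest.approx(oracle, abs=1e-9)
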