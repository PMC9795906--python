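"""Stochastic mapping tests, including a rejection-sampling oracle for the
endpoint-conditioned path sampler and consistency with marginal estimates."""

import math

import numpy as np
import pytest
from scipy import stats

from areaevo.io_core import parse_newick
from areaevo.mk_model import AreaModel, marginal_ancestral
from areaevo.simmap import (
    StochasticMap,
    _sample_conditioned_path,
    count_dispersals,
    dispersal_time_windows,
    filter_network,
    maps_to_table,
    sample_maps,
    table_to_maps,
    window_edges,
    window_index,
)
from areaevo.synthetic_data import sim_mk_tips
from tests.conftest import random_unit_tree


def rejection_sample_counts(a, b, t, q, k, n_paths, rng):
    """Forward-simulate unconditioned paths from a; keep those ending at b."""
    counts = []
    while len(counts) < n_paths:
        s, time_left, events = a, t, 0
        while True:
            wait = rng.exponential(1.0 / (q * (k - 1)))
            if wait >= time_left:
                break
            time_left -= wait
            step = int(rng.integers(k - 1))
            s = step if step < s else step + 1
            events += 1
        if s == b:
            counts.append(events)
    return np.array(counts)


def uniformization_counts(a, b, t, q, k, n_paths, rng):
    out = []
    for _ in range(n_paths):
        path = _sample_conditioned_path(a, b, t, q, k, rng)
        out.append(len(path))
    return np.array(out)


def chisquare_compare(x, y):
    """Chi-square homogeneity test on pooled bins of two count samples."""
    hi = int(max(x.max(), y.max()))
    bins = np.arange(hi + 2)
    cx = np.bincount(x, minlength=hi + 1).astype(float)
    cy = np.bincount(y, minlength=hi + 1).astype(float)
    # pool sparse upper bins so expected counts stay >= 5
    while len(cx) > 2 and (cx[-1] + cy[-1]) < 10:
        cx[-2] += cx[-1]
        cy[-2] += cy[-1]
        cx, cy = cx[:-1], cy[:-1]
    table = np.vstack([cx, cy])
    table = table[:, table.sum(axis=0) > 0]
    return stats.chi2_contingency(table).pvalue


class TestConditionedPathSampler:
    @pytest.mark.parametrize("a,b", [(0, 0), (0, 1), (1, 0), (1, 1)])
    def test_against_rejection_oracle_two_state(self, a, b):
        q, k, t = 0.8, 2, 1.0
        rng = np.random.default_rng(123)
        mine = uniformization_counts(a, b, t, q, k, 3000, rng)
        oracle = rejection_sample_counts(a, b, t, q, k, 3000, rng)
        # parity must match endpoints
        if a == b:
            assert (mine % 2 == 0).all()
        else:
            assert (mine % 2 == 1).all()
        assert chisquare_compare(mine, oracle) > 0.01

    def test_small_qt_mostly_no_events(self):
        rng = np.random.default_rng(5)
        counts = uniformization_counts(0, 0, 0.1, 0.5, 2, 2000, rng)
        # P(N=0 | A->A) = e^{-qt} / P_AA(t); qt = 0.05
        e = math.exp(-2 * 0.5 * 0.1)
        p_aa = 0.5 + 0.5 * e
        expected = math.exp(-0.5 * 0.1) / p_aa  # exit rate q(k-1) = 0.5
        assert abs((counts == 0).mean() - expected) < 0.03

    def test_zero_length_branch_same_endpoint(self):
        rng = np.random.default_rng(0)
        assert _sample_conditioned_path(1, 1, 0.0, 0.5, 3, rng) == []

    def test_zero_length_branch_mismatch_asserts(self):
        rng = np.random.default_rng(0)
        with pytest.raises(AssertionError):
            _sample_conditioned_path(0, 1, 0.0, 0.5, 3, rng)


class TestSampleMaps:
    def test_tiny_q_all_one_state_no_events(self, balanced_unit_tree):
        tips = {t: frozenset({2}) for t in balanced_unit_tree.tip_labels}
        model = AreaModel(k=4, q=1e-8)
        maps = sample_maps(balanced_unit_tree, tips, model, n_maps=20, seed=1)
        assert all(m.n_events() == 0 for m in maps)
        assert all(s == 2 for m in maps for s in m.node_states.values())

    def test_maps_validate(self, rng):
        tree = random_unit_tree(rng, 25)
        res = sim_mk_tips(tree, q=1.0, k=4, polymorphic_fraction=0.1,
                          missing_fraction=0.1, seed=7)
        model = AreaModel(k=4, q=1.0)
        for m in sample_maps(tree, res.tip_areas, model, n_maps=25, seed=2):
            m.validate(tree)

    def test_tip_pieces_consistent_with_observation(self, rng):
        tree = random_unit_tree(rng, 15)
        res = sim_mk_tips(tree, q=0.8, k=3, polymorphic_fraction=0.3, seed=3)
        model = AreaModel(k=3, q=0.8)
        for m in sample_maps(tree, res.tip_areas, model, n_maps=10, seed=4):
            for t, obs in res.tip_areas.items():
                if obs:
                    assert m.node_states[t] in obs

    def test_seed_reproducibility(self, balanced_unit_tree):
        tips = {"A": frozenset({0}), "B": frozenset({1}),
                "C": frozenset({0}), "D": frozenset({1})}
        model = AreaModel(k=2, q=0.5)
        m1 = sample_maps(balanced_unit_tree, tips, model, n_maps=5, seed=9)
        m2 = sample_maps(balanced_unit_tree, tips, model, n_maps=5, seed=9)
        assert [m.pieces for m in m1] == [m.pieces for m in m2]

    def test_node_frequencies_match_marginals(self):
        tree = parse_newick("(((A:0.4,B:0.4):0.3,C:0.7):0.3,(D:0.5,E:0.5):0.5);")
        k = 3
        tips = {"A": frozenset({0}), "B": frozenset({1}), "C": frozenset({0}),
                "D": frozenset({2}), "E": frozenset()}
        model = AreaModel(k=k, q=0.6)
        marg = marginal_ancestral(tree, tips, model)
        n = 4000
        maps = sample_maps(tree, tips, model, n_maps=n, seed=11)
        for node in [tree.root.name, tree.mrca(["A", "B"]).name]:
            freq = np.bincount([m.node_states[node] for m in maps], minlength=k) / n
            for s in range(k):
                p = marg[node][s]
                se = math.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(freq[s] - p) < max(3 * se, 0.01)

    def test_expected_event_count_unconditional(self):
        # states resimulated unconditionally: E[events] = q (k-1) L
        rng = np.random.default_rng(21)
        tree = random_unit_tree(rng, 30)
        q, k = 0.7, 4
        L = tree.total_length()
        totals = []
        for seed in range(300):
            res = sim_mk_tips(tree, q=q, k=k, seed=seed)
            totals.append(res.n_events)
        totals = np.array(totals, dtype=float)
        se = totals.std(ddof=1) / math.sqrt(len(totals))
        assert abs(totals.mean() - q * (k - 1) * L) < 3 * se


def _one_branch_map(states_ages, map_id=0):
    """Build a map with a single branch 'X' from (state, older, younger) pieces."""
    node_states = {"root": states_ages[0][0], "X": states_ages[-1][0]}
    return StochasticMap(pieces={"X": states_ages}, node_states=node_states, map_id=map_id)


class TestCountDispersals:
    def test_single_branch_a_b_a(self):
        m = _one_branch_map([(0, 1.0, 0.7), (1, 0.7, 0.4), (0, 0.4, 0.0)])
        s = count_dispersals([m], ["A", "B"])
        assert s.counts[0, 0, 1] == 1
        assert s.counts[0, 1, 0] == 1

    def test_identical_maps_collapse_quantiles(self):
        m = _one_branch_map([(0, 1.0, 0.5), (1, 0.5, 0.0)])
        s = count_dispersals([m, m, m], ["A", "B"])
        assert s.q025[0, 1] == s.median[0, 1] == s.q975[0, 1] == 1

    def test_total_conservation(self, rng):
        tree = random_unit_tree(rng, 20)
        res = sim_mk_tips(tree, q=1.2, k=3, seed=5)
        model = AreaModel(k=3, q=1.2)
        maps = sample_maps(tree, res.tip_areas, model, n_maps=15, seed=6)
        s = count_dispersals(maps, ["A", "B", "C"])
        for mi, m in enumerate(maps):
            assert s.counts[mi].sum() == m.n_events()

    def test_empty_maps_list_errors(self):
        with pytest.raises(ValueError):
            count_dispersals([], ["A"])


class TestFilterNetwork:
    def test_zero_in_range_dropped(self):
        maps = [
            _one_branch_map([(0, 1.0, 0.0)], 0),
            _one_branch_map([(0, 1.0, 0.0)], 1),
            _one_branch_map([(0, 1.0, 0.5), (1, 0.5, 0.0)], 2),
        ]
        s = count_dispersals(maps, ["A", "B"])
        assert filter_network(s) == set()

    def test_always_present_kept(self):
        maps = [_one_branch_map([(0, 1.0, 0.5), (1, 0.5, 0.0)], i) for i in range(3)]
        s = count_dispersals(maps, ["A", "B"])
        assert filter_network(s) == {("A", "B")}

    def test_no_events_empty_network(self):
        maps = [_one_branch_map([(0, 1.0, 0.0)], i) for i in range(3)]
        assert filter_network(count_dispersals(maps, ["A", "B"])) == set()


class TestTimeWindows:
    def test_event_at_055_in_window_4(self):
        # 10 windows on root age 1; ages (0.6, 0.5] form the 5th window
        # counting from the root, index 4 zero-based
        assert window_index(0.55, 1.0, 10) == 4

    def test_boundary_goes_to_older_window(self):
        assert window_index(0.6, 1.0, 10) == 3
        assert window_index(1.0, 1.0, 10) == 0
        assert window_index(0.0, 1.0, 10) == 9

    def test_window_width_six_under_calibration(self):
        edges = window_edges(60.0, 10)
        widths = np.diff(edges)
        assert np.allclose(widths, -6.0)

    def test_immigration_sums_equal_totals(self, rng):
        tree = random_unit_tree(rng, 20)
        res = sim_mk_tips(tree, q=1.5, k=3, seed=8)
        model = AreaModel(k=3, q=1.5)
        maps = sample_maps(tree, res.tip_areas, model, n_maps=12, seed=9)
        wd = dispersal_time_windows(maps, ["A", "B", "C"], root_age=1.0, n_windows=10)
        s = count_dispersals(maps, ["A", "B", "C"])
        for mi in range(len(maps)):
            for area in range(3):
                into = s.counts[mi, :, area].sum() - s.counts[mi, area, area]
                assert wd.immigration[mi, :, area].sum() == into
                out = s.counts[mi, area, :].sum() - s.counts[mi, area, area]
                assert wd.emigration[mi, :, area].sum() == out

    def test_quantile_ordering(self, rng):
        tree = random_unit_tree(rng, 15)
        res = sim_mk_tips(tree, q=1.0, k=3, seed=10)
        maps = sample_maps(tree, res.tip_areas, AreaModel(k=3, q=1.0), n_maps=30, seed=11)
        wd = dispersal_time_windows(maps, ["A", "B", "C"], root_age=1.0)
        assert (wd.imm_q025 <= wd.imm_median + 1e-12).all()
        assert (wd.imm_median <= wd.imm_q975 + 1e-12).all()


class TestSerialization:
    def test_table_round_trip(self, rng):
        tree = random_unit_tree(rng, 10)
        res = sim_mk_tips(tree, q=1.0, k=3, seed=12)
        maps = sample_maps(tree, res.tip_areas, AreaModel(k=3, q=1.0), n_maps=4, seed=13)
        codes = ["A", "B", "C"]
        df = maps_to_table(maps, codes)
        back = table_to_maps(df, tree, codes)
        assert [m.pieces for m in back] == pytest.approx(
            [m.pieces for m in maps]
        ) or _pieces_close(back, maps)


def _pieces_close(a, b, tol=1e-12):
    for ma, mb in zip(a, b):
        if set(ma.pieces) != set(mb.pieces):
            return False
        for k in ma.pieces:
            for pa, pb in zip(ma.pieces[k], mb.pieces[k]):
                if pa[0] != pb[0] or abs(pa[1] - pb[1]) > tol or abs(pa[2] - pb[2]) > tol:
                    return False
    return True
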