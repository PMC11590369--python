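"""DEC range evolution: state space, generator, pruning likelihood with
cladogenesis and epochs, ML fitting, ancestral ranges."""

from itertools import product

import numpy as np
import pytest

from morphoclock.biogeo_dec import (
    DECModel,
    ancestral_ranges,
    cladogenetic_splits,
    dec_log_likelihood,
    dec_rate_matrix,
    enumerate_ranges,
    fit_dec,
)
from morphoclock.io_formats import ConnectivityModel, RangeTable
from morphoclock.synthetic_data import simulate_fbd_tree, simulate_ranges
from morphoclock.tree_priors import FBDParams
from morphoclock.trees import TimeTree


def propagator_by_squaring(Q, t, n_doublings=22):
    """(I + Q t / 2^n)^(2^n): discretized propagator, independent of expm."""
    P = np.eye(Q.shape[0]) + Q * (t / 2.0**n_doublings)
    for _ in range(n_doublings):
        P = P @ P
    return P


def brute_force_dec(tree, ranges, model):
    """Sum over every internal-node range assignment and split scenario."""
    space = model.space()
    conn = model.connectivity
    S = space.n_states

    def branch_P(age_child, age_parent):
        cuts = {age_child, age_parent}
        for start, end, _ in conn.epochs:
            for b in (start, end):
                if age_child < b < age_parent:
                    cuts.add(b)
        edges = sorted(cuts)
        P = np.eye(S)
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = conn.at_age(0.5 * (lo + hi))
            Q = dec_rate_matrix(space, model.d, model.e, m)
            P = propagator_by_squaring(Q, hi - lo) @ P
        return P  # rows: state at parent end; columns: state at child end

    # orientation: P[x, y] = P(child end = y | start = x); stack top-down
    def branch_P_oriented(age_child, age_parent):
        cuts = {age_child, age_parent}
        for start, end, _ in conn.epochs:
            for b in (start, end):
                if age_child < b < age_parent:
                    cuts.add(b)
        edges = sorted(cuts)
        P = np.eye(S)
        for lo, hi in reversed(list(zip(edges[:-1], edges[1:]))):
            m = conn.at_age(0.5 * (lo + hi))
            Q = dec_rate_matrix(space, model.d, model.e, m)
            P = P @ propagator_by_squaring(Q, hi - lo)
        return P

    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tips = {int(v): space.index[ranges.area_set(tree.labels[int(v)])]
            for v in tree.tip_indices}
    prior = np.zeros(S)
    prior[1:] = 1.0 / (S - 1)
    P_branch = {
        v: branch_P_oriented(float(tree.ages[v]), float(tree.ages[int(tree.parent[v])]))
        for v in range(tree.n_nodes)
        if tree.parent[v] >= 0
    }
    splits_of = {
        i: cladogenetic_splits(space, space.states[i], model.wide_vicariance)
        for i in range(S)
        if space.states[i]
    }
    total = 0.0
    for assign in product(range(1, S), repeat=len(internals)):
        st = dict(zip(internals, assign))
        p_topo = prior[st[tree.root]]
        for v in internals:
            kids = tree.children[v]
            splits = splits_of[st[v]]
            w = 1.0 / len(splits)
            acc = 0.0
            for l, r in splits:
                term = 1.0
                for child, start_set in zip(kids, (l, r)):
                    start_idx = space.index[start_set]
                    end_idx = (
                        tips[child] if tree.is_tip(child) else st[child]
                    )
                    term *= P_branch[child][start_idx, end_idx]
                acc += term
            p_topo *= w * acc
        total += p_topo
    return float(np.log(total))


class TestStateSpace:
    def test_two_area_enumeration(self):
        space = enumerate_ranges(2, 2)
        assert space.states == [
            frozenset(), frozenset({0}), frozenset({1}), frozenset({0, 1})
        ]

    def test_single_area_cap_on_13_areas(self):
        assert enumerate_ranges(13, 1).n_states == 14

    def test_binomial_sum_for_cap_three(self):
        assert enumerate_ranges(13, 3).n_states == 1 + 13 + 78 + 286

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError):
            enumerate_ranges(3, 0)


class TestRateMatrix:
    def test_single_area_rates(self):
        space = enumerate_ranges(2, 2)
        Q = dec_rate_matrix(space, d=0.3, e=0.1, connectivity=np.ones((2, 2), int))
        i = space.index[frozenset({0})]
        assert Q[i, space.index[frozenset({0, 1})]] == pytest.approx(0.3)
        assert Q[i, space.index[frozenset()]] == pytest.approx(0.1)

    def test_no_connectivity_no_expansion(self):
        space = enumerate_ranges(3, 3)
        Q = dec_rate_matrix(space, 0.5, 0.1, np.eye(3, dtype=int))
        for i, R in enumerate(space.states):
            for j, R2 in enumerate(space.states):
                if len(R2) > len(R):
                    assert Q[i, j] == 0.0

    def test_zero_rates_zero_matrix(self):
        space = enumerate_ranges(2, 2)
        Q = dec_rate_matrix(space, 0.0, 0.0, np.ones((2, 2), int))
        assert np.allclose(Q, 0.0)

    def test_rows_sum_to_zero_and_propagator_stochastic(self, rng):
        space = enumerate_ranges(4, 3)
        m = (rng.random((4, 4)) < 0.7).astype(int)
        np.fill_diagonal(m, 1)
        Q = dec_rate_matrix(space, 0.2, 0.07, m)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        from scipy.linalg import expm

        P = expm(Q * 3.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P.min() >= -1e-12


class TestLikelihood:
    def test_no_events_reduce_to_root_prior_mass(self):
        t = TimeTree([-1, 0, 0], [5.0, 0.0, 0.0], ["", "A", "B"])
        ranges = RangeTable(["X", "Y"], {"A": np.array([1, 0]), "B": np.array([1, 0])})
        model = DECModel(["X", "Y"], 0.0, 0.0, 2)
        # d = e = 0: only narrow sympatry from {X} is possible
        assert dec_log_likelihood(t, ranges, model) == pytest.approx(np.log(1 / 3))

    def test_three_taxon_brute_force_oracle(self, three_taxon_tree, rng):
        areas = ["X", "Y", "Z"]
        for trial in range(4):
            pres = {}
            for lab in "ABC":
                size = int(rng.integers(1, 3))  # respect the 2-area cap
                vec = np.zeros(3, dtype=int)
                vec[rng.choice(3, size=size, replace=False)] = 1
                pres[lab] = vec
            ranges = RangeTable(areas, pres)
            model = DECModel(areas, 0.15, 0.08, 2)
            mine = dec_log_likelihood(three_taxon_tree, ranges, model)
            ref = brute_force_dec(three_taxon_tree, ranges, model)
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_epoch_split_equals_product_of_exponentials(self, three_taxon_tree, rng):
        # a boundary mid-branch must not change the likelihood when both
        # epochs share the same connectivity (semigroup property)
        areas = ["X", "Y"]
        ranges = RangeTable(
            areas, {"A": np.array([1, 0]), "B": np.array([0, 1]), "C": np.array([1, 1])}
        )
        m = np.ones((2, 2), dtype=int)
        one_epoch = ConnectivityModel(areas, [(100.0, 0.0, m)])
        split_epoch = ConnectivityModel(areas, [(100.0, 0.7, m), (0.7, 0.0, m)])
        l1 = dec_log_likelihood(
            three_taxon_tree, ranges, DECModel(areas, 0.2, 0.1, 2, one_epoch)
        )
        l2 = dec_log_likelihood(
            three_taxon_tree, ranges, DECModel(areas, 0.2, 0.1, 2, split_epoch)
        )
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_epoch_connectivity_changes_likelihood(self, three_taxon_tree):
        areas = ["X", "Y"]
        ranges = RangeTable(
            areas, {"A": np.array([1, 0]), "B": np.array([0, 1]), "C": np.array([1, 1])}
        )
        open_m = np.ones((2, 2), dtype=int)
        closed_m = np.eye(2, dtype=int)
        mixed = ConnectivityModel(areas, [(100.0, 1.0, closed_m), (1.0, 0.0, open_m)])
        l_open = dec_log_likelihood(
            three_taxon_tree, ranges,
            DECModel(areas, 0.2, 0.1, 2, ConnectivityModel.uniform(areas)),
        )
        l_mixed = dec_log_likelihood(
            three_taxon_tree, ranges, DECModel(areas, 0.2, 0.1, 2, mixed)
        )
        assert l_mixed < l_open  # late-opening world makes disjunction harder

    def test_likelihood_invariant_to_area_permutation(self, three_taxon_tree, rng):
        areas = ["X", "Y", "Z"]
        pres = {"A": np.array([1, 0, 0]), "B": np.array([0, 1, 1]), "C": np.array([1, 1, 0])}
        m = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]])
        conn = ConnectivityModel(areas, [(100.0, 0.0, m)])
        base = dec_log_likelihood(
            three_taxon_tree, RangeTable(areas, pres),
            DECModel(areas, 0.2, 0.08, 2, conn),
        )
        perm = [2, 0, 1]
        areas_p = [areas[i] for i in perm]
        pres_p = {k: v[perm] for k, v in pres.items()}
        m_p = m[np.ix_(perm, perm)]
        conn_p = ConnectivityModel(areas_p, [(100.0, 0.0, m_p)])
        permuted = dec_log_likelihood(
            three_taxon_tree, RangeTable(areas_p, pres_p),
            DECModel(areas_p, 0.2, 0.08, 2, conn_p),
        )
        assert permuted == pytest.approx(base, abs=1e-10)

    def test_oversized_tip_range_suggests_larger_cap(self, three_taxon_tree):
        areas = ["X", "Y", "Z"]
        ranges = RangeTable(
            areas,
            {"A": np.array([1, 1, 1]), "B": np.array([1, 0, 0]), "C": np.array([0, 1, 0])},
        )
        with pytest.raises(ValueError, match="raise the cap"):
            dec_log_likelihood(three_taxon_tree, ranges, DECModel(areas, 0.1, 0.1, 2))


class TestFitAndAncestralRanges:
    def test_shared_range_pins_extinction_at_zero(self, five_taxon_tree):
        areas = ["X", "Y"]
        ranges = RangeTable(
            areas, {lab: np.array([1, 0]) for lab in five_taxon_tree.tip_labels}
        )
        with pytest.warns(UserWarning, match="bound"):
            fitted = fit_dec(five_taxon_tree, ranges, DECModel(areas, 0.1, 0.1, 2))
        assert fitted.e == pytest.approx(1e-6, rel=1.0)
        anc = ancestral_ranges(five_taxon_tree, ranges, fitted)
        for v in range(five_taxon_tree.n_nodes):
            best_range, p = anc[v][0]
            assert best_range == frozenset({0})
            assert p > 0.95

    def test_connectivity_zero_block_receives_no_dispersal(self, rng):
        # two 2-area blocks, never connected: simulated tip ranges must
        # stay inside the root's block
        areas = ["X1", "X2", "Y1", "Y2"]
        m = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=int
        )
        conn = ConnectivityModel(areas, [(1000.0, 0.0, m)])
        model = DECModel(areas, 0.4, 0.05, 2, conn)
        tree, _ = simulate_fbd_tree(FBDParams(0.3, 0.2, 0.2, 1.0), 8.0, seed=3, min_tips=6)
        for seed in range(5):
            table, node_ranges = simulate_ranges(tree, model, seed=seed)
            root_block = 0 if min(node_ranges[tree.root]) < 2 else 1
            for vec in table.presence.values():
                occupied = set(np.flatnonzero(vec))
                assert all((a < 2) == (root_block == 0) for a in occupied)

    def test_parameter_recovery_on_simulated_ranges(self):
        # moderate-size recovery: ML (d, e) within a factor consistent with
        # the information in ~40 tips
        d_true, e_true = 0.08, 0.03
        areas = ["X", "Y", "Z", "W"]
        model = DECModel(areas, d_true, e_true, 3)
        tree, _ = simulate_fbd_tree(
            FBDParams(0.45, 0.2, 0.0, 1.0), 10.0, seed=21, min_tips=35, max_tips=60
        )
        table, _ = simulate_ranges(tree, model, seed=9)
        survivors = tree.prune_to(table.presence.keys())  # extinct tips dropped
        fitted = fit_dec(survivors, table, DECModel(areas, 0.01, 0.01, 3))
        assert fitted.d == pytest.approx(d_true, rel=0.6)
        assert fitted.e == pytest.approx(e_true, abs=0.05)


class TestCladogeneticSplits:
    def test_single_area_narrow_sympatry_only(self):
        space = enumerate_ranges(3, 2)
        R = frozenset({1})
        assert cladogenetic_splits(space, R) == [(R, R)]

    def test_two_area_range_has_sympatry_and_vicariance(self):
        space = enumerate_ranges(3, 2)
        R = frozenset({0, 1})
        splits = set(cladogenetic_splits(space, R))
        a, b, ab = frozenset({0}), frozenset({1}), R
        assert (a, ab) in splits and (ab, a) in splits  # subset sympatry
        assert (a, b) in splits and (b, a) in splits  # vicariance
        assert (ab, ab) not in splits

    def test_wide_vicariance_only_with_flag(self):
        space = enumerate_ranges(5, 4)
        R = frozenset({0, 1, 2, 3})
        narrow = set(cladogenetic_splits(space, R, wide_vicariance=False))
        wide = set(cladogenetic_splits(space, R, wide_vicariance=True))
        two_two = (frozenset({0, 1}), frozenset({2, 3}))
        assert two_two not in narrow
        assert two_two in wide
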