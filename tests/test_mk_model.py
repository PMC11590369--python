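"""Mk(v) likelihood: transition matrices, discrete gamma, pruning vs
brute-force enumeration, and the ascertainment correction."""

from itertools import product

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from morphoclock import mk_model as mk
from morphoclock.io_formats import CharacterMatrix
from morphoclock.trees import TimeTree

from conftest import random_dated_tree


def mk_rate_matrix(k):
    Q = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(Q, -1.0)
    return Q


def enumeration_log_likelihood(tree, eff, column, k, rates):
    """Sum over all internal-state assignments with expm propagators."""
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tipsets = {int(v): column[tree.labels[int(v)]] for v in tree.tip_indices}
    Q = mk_rate_matrix(k)
    total = 0.0
    for r in rates:
        P = {v: expm(Q * eff[v] * r) for v in range(tree.n_nodes)}
        for assign in product(range(k), repeat=len(internals)):
            st = dict(zip(internals, assign))
            p = 1.0 / k
            for v in range(tree.n_nodes):
                par = int(tree.parent[v])
                if par < 0:
                    continue
                if tree.is_tip(v):
                    p *= sum(P[v][st[par], s] for s in tipsets[v])
                else:
                    p *= P[v][st[par], st[v]]
            total += p
    return float(np.log(total / len(rates)))


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(mk.mk_transition_matrix(2, 0.0), np.eye(2))

    def test_long_time_reaches_uniform_stationary(self):
        P = mk.mk_transition_matrix(4, 1e4)
        assert np.allclose(P, 0.25, atol=1e-12)

    def test_p_same_matches_matrix_exponential(self):
        P = mk.mk_transition_matrix(2, 0.5)
        ref = expm(mk_rate_matrix(2) * 0.5)
        assert P[0, 0] == pytest.approx(0.68394, abs=1e-5)
        assert np.allclose(P, ref, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 7))
            t = float(rng.exponential(1.0))
            assert np.allclose(mk.mk_transition_matrix(k, t).sum(axis=1), 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mk.mk_transition_matrix(2, -0.1)


class TestDiscreteGamma:
    def test_single_category_is_unit(self):
        assert mk.discrete_gamma_rates(2.0, 1) == pytest.approx([1.0])

    def test_large_shape_concentrates_at_mean(self):
        rates = mk.discrete_gamma_rates(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)

    def test_mean_is_exactly_one(self, rng):
        for alpha in (0.1, 0.5, 1.0, 7.3):
            assert mk.discrete_gamma_rates(alpha, 4).mean() == pytest.approx(1.0)

    def test_category_means_match_quadrature(self):
        alpha, n = 0.5, 4
        rates = mk.discrete_gamma_rates(alpha, n)
        edges = gamma_dist.ppf(np.linspace(0, 1, n + 1), alpha, scale=1 / alpha)
        edges[-1] = np.inf
        for i in range(n):
            num, _ = quad(
                lambda x: x * gamma_dist.pdf(x, alpha, scale=1 / alpha),
                edges[i],
                edges[i + 1],
            )
            assert rates[i] == pytest.approx(n * num, rel=1e-6)


class TestCharacterLikelihood:
    def test_zero_lengths_reduce_to_root_frequency(self, three_taxon_tree):
        t = three_taxon_tree
        col = {x: frozenset([0]) for x in "ABC"}
        lnl = mk.character_log_likelihood(t, np.zeros(t.n_nodes), col, 3)
        assert lnl == pytest.approx(np.log(1.0 / 3))

    def test_all_missing_marginalizes_to_one(self, three_taxon_tree, rng):
        t = three_taxon_tree
        col = {x: frozenset([0, 1]) for x in "ABC"}
        eff = rng.exponential(0.5, t.n_nodes)
        lnl = mk.character_log_likelihood(t, eff, col, 2)
        assert lnl == pytest.approx(0.0, abs=1e-12)

    def test_missing_taxon_raises_key_error(self, three_taxon_tree):
        with pytest.raises(KeyError):
            mk.character_log_likelihood(
                three_taxon_tree, np.ones(5), {"A": frozenset([0])}, 2
            )

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_pruning_equals_enumeration(self, k, rng):
        for _ in range(8):
            t = random_dated_tree(int(rng.integers(3, 7)), rng, fossil_prob=0.2)
            eff = np.abs(rng.normal(0.3, 0.3, t.n_nodes))
            col = {}
            for i in t.tip_indices:
                size = 1 if rng.random() < 0.8 else 2
                col[t.labels[int(i)]] = frozenset(
                    rng.choice(k, size=min(size, k), replace=False).tolist()
                )
            rates = mk.discrete_gamma_rates(float(rng.uniform(0.3, 2.0)), 3)
            mine = mk.character_log_likelihood(t, eff, col, k, rates)
            ref = enumeration_log_likelihood(t, eff, col, k, rates)
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_invariant_to_taxon_order(self, rng):
        t = random_dated_tree(5, rng)
        eff = np.abs(rng.normal(0.4, 0.2, t.n_nodes))
        cols = [
            {lab: frozenset([int(rng.integers(2))]) for lab in t.tip_labels}
            for _ in range(5)
        ]
        counts = [2] * 5
        taxa = sorted(t.tip_labels)
        chars_a = [[cols[j][x] for j in range(5)] for x in taxa]
        chars_b = [[cols[j][x] for j in range(5)] for x in taxa[::-1]]
        ma = CharacterMatrix(taxa, chars_a, counts, coding="all")
        mb = CharacterMatrix(taxa[::-1], chars_b, counts, coding="all")
        assert mk.matrix_log_likelihood(t, eff, ma) == pytest.approx(
            mk.matrix_log_likelihood(t, eff, mb)
        )

    def test_gamma_mixture_converges_to_single_rate(self, five_taxon_tree, rng):
        t = five_taxon_tree
        eff = np.abs(rng.normal(0.3, 0.2, t.n_nodes))
        col = {lab: frozenset([int(rng.integers(2))]) for lab in t.tip_labels}
        with_gamma = mk.character_log_likelihood(
            t, eff, col, 2, mk.discrete_gamma_rates(1e8, 4)
        )
        single = mk.character_log_likelihood(t, eff, col, 2, np.ones(1))
        assert with_gamma == pytest.approx(single, abs=1e-6)


class TestAscertainmentCorrection:
    def test_two_taxon_closed_form(self):
        t = TimeTree([-1, 0, 0], [1.0, 0.0, 0.0], ["", "A", "B"])
        eff = np.array([0.0, 0.5, 0.5])
        m = CharacterMatrix(
            ["A", "B"],
            [[frozenset([0])], [frozenset([1])]],
            [2],
            coding="variable",
        )
        raw = mk.character_log_likelihood(
            t, eff, {"A": frozenset([0]), "B": frozenset([1])}, 2, np.ones(1)
        )
        ln_same = mk.character_log_likelihood(
            t, eff, {"A": frozenset([0]), "B": frozenset([0])}, 2, np.ones(1)
        )
        expected = raw - np.log1p(-2.0 * np.exp(ln_same))
        assert mk.matrix_log_likelihood(t, eff, m, alpha=None) == pytest.approx(
            expected
        )

    def test_all_coding_equals_raw(self, five_taxon_tree, rng):
        t = five_taxon_tree
        eff = np.abs(rng.normal(0.3, 0.2, t.n_nodes))
        taxa = t.tip_labels
        chars = [[frozenset([int(rng.integers(2))]) for _ in range(6)] for _ in taxa]
        m = CharacterMatrix(taxa, chars, [2] * 6, coding="all")
        lik = mk.MkLikelihood(t, m)
        raw = lik.per_character_log_likelihoods(t, eff, alpha=1.0).sum()
        assert lik.log_likelihood(t, eff, alpha=1.0) == pytest.approx(float(raw))

    def test_corrected_always_below_raw(self, rng):
        t = random_dated_tree(8, rng)
        eff = np.abs(rng.normal(0.3, 0.2, t.n_nodes))
        taxa = sorted(t.tip_labels)
        while True:  # reject constant columns so variable coding is legal
            chars = [
                [frozenset([int(rng.integers(2))]) for _ in range(50)] for _ in taxa
            ]
            cols_ok = all(
                len({chars[i][j] for i in range(len(taxa))}) > 1 for j in range(50)
            )
            if cols_ok:
                break
        m = CharacterMatrix(taxa, chars, [2] * 50, coding="variable")
        lik = mk.MkLikelihood(t, m)
        raw = float(lik.per_character_log_likelihoods(t, eff, alpha=1.0).sum())
        corrected = lik.log_likelihood(t, eff, alpha=1.0)
        assert corrected > raw  # dividing by (1 - P(const)) < 1 raises each term
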