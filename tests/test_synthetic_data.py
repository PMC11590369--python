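"""Generators: FBD forward simulation, clocked Mk characters, DEC ranges."""

import numpy as np
import pytest
from scipy.linalg import expm

from morphoclock.biogeo_dec import DECModel, dec_rate_matrix, enumerate_ranges
from morphoclock.clock_models import effective_lengths, sample_branch_rates
from morphoclock.io_formats import ConnectivityModel
from morphoclock.synthetic_data import (
    _gillespie_branch,
    simulate_characters,
    simulate_fbd_tree,
    simulate_ranges,
    study_connectivity,
)
from morphoclock.tree_priors import FBDParams


class TestFBDTreeSimulator:
    def test_yule_extant_count_matches_expectation(self):
        # pure birth from 2 crown lineages over T: E[tips] = 2 e^{lam T}
        lam, T = 1.0, 3.0
        counts = [
            simulate_fbd_tree(
                FBDParams(lam, 0.0, 0.0, 1.0), T, seed=i, min_tips=2
            )[0].n_tips
            for i in range(400)
        ]
        expected = 2 * np.exp(lam * T)
        se = np.std(counts) / np.sqrt(len(counts))
        # conditioning on >=2 surviving tips is immaterial for pure birth
        assert np.mean(counts) == pytest.approx(expected, abs=3 * se)

    def test_zero_fossil_rate_no_fossil_tips(self):
        tree, _ = simulate_fbd_tree(FBDParams(0.3, 0.4, 0.0, 1.0), 5.0, seed=3)
        assert all(not lab.startswith("f") for lab in tree.tip_labels)
        assert tree.sampled_ancestor.sum() == 0

    def test_same_seed_identical_tree(self):
        p = FBDParams(0.1, 0.3, 0.5, 1.0)
        t1, m1 = simulate_fbd_tree(p, 10.0, seed=42)
        t2, m2 = simulate_fbd_tree(p, 10.0, seed=42)
        assert np.array_equal(t1.ages, t2.ages)
        assert t1.labels == t2.labels
        assert m1.true_node_ages == m2.true_node_ages

    def test_fossils_on_surviving_lineages_become_sampled_ancestors(self):
        found_sa = False
        for seed in range(30):
            tree, _ = simulate_fbd_tree(
                FBDParams(0.2, 0.3, 0.6, 1.0), 8.0, seed=seed, min_tips=5
            )
            tree.validate()
            if tree.sampled_ancestor.sum() > 0:
                found_sa = True
                for i in np.flatnonzero(tree.sampled_ancestor):
                    p = int(tree.parent[int(i)])
                    assert tree.ages[i] == pytest.approx(tree.ages[p])
        assert found_sa

    def test_calibration_windows_contain_true_ages(self):
        tree, _ = simulate_fbd_tree(FBDParams(0.1, 0.4, 0.6, 1.0), 10.0, seed=7)
        assert tree.calibrations  # fossil-rich settings must calibrate tips
        for lab, (lo, hi) in tree.calibrations.items():
            age = tree.ages[tree.tip_index(lab)]
            assert lo <= age <= hi


class TestCharacterSimulator:
    def test_zero_lengths_rejected_under_variable_only(self, five_taxon_tree):
        with pytest.raises(ValueError, match="constant"):
            simulate_characters(
                five_taxon_tree, np.zeros(five_taxon_tree.n_nodes), 1.0, 5, seed=1
            )

    def test_variable_only_matrix_has_no_constant_column(self, five_taxon_tree, rng):
        eff = np.abs(rng.normal(0.2, 0.1, five_taxon_tree.n_nodes))
        m = simulate_characters(five_taxon_tree, eff, 1.0, 40, seed=2)
        assert m.coding == "variable"
        assert not any(m.is_constant(j) for j in range(m.n_chars))

    def test_all_coding_keeps_constants(self, five_taxon_tree, rng):
        eff = np.full(five_taxon_tree.n_nodes, 1e-4)
        m = simulate_characters(
            five_taxon_tree, eff, 1.0, 30, seed=3, variable_only=False
        )
        assert m.coding == "all"
        assert any(m.is_constant(j) for j in range(m.n_chars))

    def test_long_branches_approach_uniform_tip_frequencies(self, five_taxon_tree):
        from scipy.stats import chisquare

        eff = np.full(five_taxon_tree.n_nodes, 50.0)
        m = simulate_characters(
            five_taxon_tree, eff, 1e6, 400, seed=4,
            state_counts=[3] * 400, variable_only=False,
        )
        counts = np.zeros(3)
        for row in m.chars:
            for cell in row:
                counts[next(iter(cell))] += 1
        assert chisquare(counts).pvalue > 0.01

    def test_seed_determinism_and_missingness(self, five_taxon_tree, rng):
        eff = np.abs(rng.normal(0.3, 0.1, five_taxon_tree.n_nodes))
        a = simulate_characters(five_taxon_tree, eff, 1.0, 20, seed=5, missing_prob=0.2)
        b = simulate_characters(five_taxon_tree, eff, 1.0, 20, seed=5, missing_prob=0.2)
        assert a.chars == b.chars
        n_missing = sum(
            1
            for i in range(a.n_taxa)
            for j in range(a.n_chars)
            if a.chars[i][j] == frozenset(range(a.state_counts[j]))
        )
        assert n_missing > 0


class TestModelSelectionSanity:
    def test_stepping_stone_prefers_generating_clock_under_strong_variation(self):
        """Data simulated under ILN with strong branch-rate variation
        (nu = 2) should yield a positive ILN-vs-strict Bayes factor in at
        least 8 of 10 replicates."""
        import warnings

        from morphoclock.clock_models import ClockConfig, sample_branch_rates
        from morphoclock.mcmc_engine import MCMCConfig
        from morphoclock.model_selection import (
            SteppingStoneConfig,
            stepping_stone_clock_model,
        )
        from morphoclock.tree_priors import RootCalibration

        rng = np.random.default_rng(55)
        wins = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(10):
                tree, _ = simulate_fbd_tree(
                    FBDParams(0.05, 0.5, 0.3, 1.0), 37.6,
                    seed=int(rng.integers(2**31 - 1)), min_tips=14, max_tips=22,
                )
                br = sample_branch_rates(
                    "ILN", tree, 2.0,
                    np.random.default_rng(int(rng.integers(2**31 - 1))),
                )
                eff = effective_lengths(tree, 0.4426, br)
                mat = simulate_characters(
                    tree, eff, 1.0, 80, seed=int(rng.integers(2**31 - 1))
                )
                ss = SteppingStoneConfig(
                    n_steps=6, burn_in_steps=1, generations_per_step=2500
                )
                mlnl = {}
                for model in ("strict", "ILN"):
                    clock = ClockConfig(model=model)
                    est, _ = stepping_stone_clock_model(
                        mat, tree, clock, ss,
                        seed=int(rng.integers(2**31 - 1)),
                        mcmc_config=MCMCConfig(
                            clock=clock,
                            root_calibration=RootCalibration(34.0, 41.2),
                        ),
                    )
                    mlnl[model] = est
                wins += mlnl["ILN"] > mlnl["strict"]
        assert wins >= 8


class TestRangeSimulator:
    def test_zero_rates_inherit_root_range(self, five_taxon_tree):
        model = DECModel(["X", "Y", "Z"], 0.0, 0.0, 2)
        table, node_ranges = simulate_ranges(five_taxon_tree, model, seed=1)
        root_range = node_ranges[five_taxon_tree.root]
        if len(root_range) == 1:
            for taxon in table.presence:
                assert table.area_set(taxon) == root_range
        else:
            # cladogenesis still splits multi-area ranges; tips must be subsets
            for taxon in table.presence:
                assert table.area_set(taxon) <= root_range

    def test_gillespie_occupancy_matches_matrix_exponential(self, rng):
        space = enumerate_ranges(2, 2)
        conn = ConnectivityModel.uniform(["X", "Y"])
        model = DECModel(["X", "Y"], 0.25, 0.1, 2, conn)
        start = frozenset({0})
        T = 2.0
        counts = np.zeros(space.n_states)
        n = 4000
        for i in range(n):
            end = _gillespie_branch(start, T, 0.0, model, rng)
            counts[space.index[end]] += 1
        Q = dec_rate_matrix(space, 0.25, 0.1, np.ones((2, 2), int))
        expected = expm(Q * T)[space.index[start]]
        assert np.abs(counts / n - expected).max() < 0.02

    def test_never_connected_blocks_stay_separate_across_epochs(self):
        # areas {X1, X2} and {Y1, Y2} are never connected in any epoch, so
        # no lineage can ever occupy areas from both blocks
        areas = ["X1", "X2", "Y1", "Y2"]
        within = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=int
        )
        sparser = np.eye(4, dtype=int)
        conn = ConnectivityModel(
            areas, [(40.0, 20.0, within), (20.0, 10.0, sparser), (10.0, 0.0, within)]
        )
        model = DECModel(areas, 0.3, 0.02, 2, conn)
        from morphoclock.synthetic_data import simulate_fbd_tree

        tree, _ = simulate_fbd_tree(
            FBDParams(0.08, 0.4, 0.3, 1.0), 40.0, seed=9, min_tips=10, max_tips=40
        )
        for seed in range(4):
            table, node_ranges = simulate_ranges(tree, model, seed=seed)
            blocks = {0: {0, 1}, 1: {2, 3}}
            root_block = 0 if min(node_ranges[tree.root]) < 2 else 1
            for taxon in table.presence:
                assert table.area_set(taxon) <= blocks[root_block]

    def test_study_connectivity_shape(self):
        conn = study_connectivity()
        assert len(conn.areas) == 13
        assert len(conn.epochs) == 3
        # oldest epoch isolates sub-Saharan Africa from Arabia
        old = conn.epochs[0][2]
        i, j = conn.areas.index("AR"), conn.areas.index("EA")
        assert old[i, j] == 0
        young = conn.epochs[-1][2]
        assert young[i, j] == 1

    def test_same_seed_identical_ranges(self, five_taxon_tree):
        model = DECModel(["X", "Y", "Z"], 0.1, 0.05, 2)
        t1, n1 = simulate_ranges(five_taxon_tree, model, seed=11)
        t2, n2 = simulate_ranges(five_taxon_tree, model, seed=11)
        assert n1 == n2
        assert {k: tuple(v) for k, v in t1.presence.items()} == {
            k: tuple(v) for k, v in t2.presence.items()
        }
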