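import numpy as np
import pytest

import cpo
from cpo import SimulationConfig, ValidationError
from cpo.simulate import internal_node_tips, random_clade, simulate_covariates, simulate_diet, simulate_tree


class TestSimulateTree:
    def test_internal_node_count(self):
        tree = simulate_tree(4, seed=0)
        assert sum(1 for _ in tree.preorder_internal_node_iter()) == 3

    def test_deterministic_newick(self):
        a = simulate_tree(10, seed=5).as_string(schema="newick")
        b = simulate_tree(10, seed=5).as_string(schema="newick")
        assert a == b

    def test_different_seed_changes_topology(self):
        a = simulate_tree(10, seed=1).as_string(schema="newick")
        b = simulate_tree(10, seed=2).as_string(schema="newick")
        assert a != b

    def test_25_species_tree_combinatorics(self):
        tree = simulate_tree(25, seed=3)
        assert sum(1 for _ in tree.leaf_node_iter()) == 25
        assert sum(1 for _ in tree.preorder_internal_node_iter()) == 24
        X = cpo.clade_matrix_from_tree(tree)
        assert X.n_clades <= 23  # root excluded; duplicates collapsed

    def test_random_clade_size_range(self):
        tree = simulate_tree(20, seed=4)
        rng = np.random.default_rng(0)
        label = random_clade(tree, rng, min_size=5, max_size=10)
        assert 5 <= len(internal_node_tips(tree)[label]) <= 10


class TestSimulateDiet:
    def test_null_model_rows_share_expected_profile(self):
        """With zero Brownian noise and no effects every species has the
        same multinomial probabilities, so at large counts the per-species
        profiles converge to the common (uniform) profile."""
        cfg = SimulationConfig(n_species=10, n_prey_categories=4,
                               brownian_sigma=0.0, items_per_species=5000.0,
                               tree_seed=0, data_seed=0)
        ds = cpo.simulate_dataset(cfg)
        props = ds.Y.row_proportions()
        np.testing.assert_allclose(props, 0.25, atol=0.05)

    def test_planted_effect_raises_target_category_share(self):
        tree = simulate_tree(20, seed=1)
        rng = np.random.default_rng(1)
        clade = random_clade(tree, rng, min_size=6, max_size=10)
        members = set(internal_node_tips(tree)[clade])
        effect = np.zeros(5)
        effect[2] = 3.0
        cfg = SimulationConfig(n_species=20, n_prey_categories=5,
                               clade_effects={clade: effect},
                               brownian_sigma=0.1, items_per_species=200.0,
                               tree_seed=1, data_seed=2)
        ds = simulate_diet(tree, cfg)
        props = ds.Y.row_proportions()
        in_clade = [i for i, s in enumerate(ds.Y.species_ids) if s in members]
        out_clade = [i for i, s in enumerate(ds.Y.species_ids) if s not in members]
        assert props[in_clade, 2].mean() > props[out_clade, 2].mean() + 0.3

    def test_truth_records_members_and_effects(self):
        tree = simulate_tree(12, seed=2)
        clade = random_clade(tree, np.random.default_rng(0), min_size=3)
        cfg = SimulationConfig(n_species=12, n_prey_categories=4,
                               clade_effects={clade: [1.0, 0, 0, 0]},
                               tree_seed=2, data_seed=3)
        ds = simulate_diet(tree, cfg)
        assert ds.truth["clade_effects"][clade]["members"] == \
            internal_node_tips(tree)[clade]

    def test_unknown_effect_clade_rejected(self):
        tree = simulate_tree(8, seed=0)
        cfg = SimulationConfig(n_species=8, n_prey_categories=4,
                               clade_effects={"nope": [1.0, 0, 0, 0]})
        with pytest.raises(ValidationError, match="not a labeled tree node"):
            simulate_diet(tree, cfg)

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_species=10, n_prey_categories=4,
                               tree_seed=7, data_seed=7)
        a = cpo.simulate_dataset(cfg)
        b = cpo.simulate_dataset(cfg)
        np.testing.assert_array_equal(a.Y.counts, b.Y.counts)
        assert a.covariates.habitat == b.covariates.habitat


class TestSimulateCovariates:
    def test_zero_sigma_gives_constant_svl(self):
        tree = simulate_tree(8, seed=1)
        cfg = SimulationConfig(n_species=8, svl_brownian_sigma=0.0)
        cov = simulate_covariates(tree, cfg, seed=0)
        np.testing.assert_allclose(cov.svl_mm, cov.svl_mm[0])

    def test_iid_habitat_independent_of_clades(self):
        """i.i.d. habitat: sister species share a habitat about as often as
        the marginal frequency predicts (1/5 per level on average)."""
        share = 0
        pairs = 0
        for rep in range(60):
            tree = simulate_tree(12, seed=rep)
            cfg = SimulationConfig(n_species=12, habitat_tree_correlated=False)
            cov = simulate_covariates(tree, cfg, seed=rep)
            hab = dict(zip(cov.species_ids, cov.habitat))
            for node in tree.preorder_internal_node_iter():
                kids = node.child_nodes()
                if all(k.is_leaf() for k in kids) and len(kids) == 2:
                    pairs += 1
                    if hab[kids[0].taxon.label] == hab[kids[1].taxon.label]:
                        share += 1
        assert 0.10 < share / pairs < 0.35  # around 0.2 under independence

    def test_tree_correlated_habitat_shares_more_than_iid(self):
        def sister_share(tree_corr):
            share = pairs = 0
            for rep in range(60):
                tree = simulate_tree(12, seed=rep)
                cfg = SimulationConfig(n_species=12, habitat_tree_correlated=tree_corr,
                                       habitat_switch_prob=0.2)
                cov = simulate_covariates(tree, cfg, seed=rep)
                hab = dict(zip(cov.species_ids, cov.habitat))
                for node in tree.preorder_internal_node_iter():
                    kids = node.child_nodes()
                    if all(k.is_leaf() for k in kids) and len(kids) == 2:
                        pairs += 1
                        if hab[kids[0].taxon.label] == hab[kids[1].taxon.label]:
                            share += 1
            return share / pairs
        assert sister_share(True) > sister_share(False) + 0.2

    def test_habitat_levels_legal(self):
        tree = simulate_tree(10, seed=3)
        cov = simulate_covariates(tree, SimulationConfig(n_species=10), seed=3)
        assert set(cov.habitat) <= set(cpo.HABITAT_LEVELS)
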