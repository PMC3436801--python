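"""Simulator behaviour, ground truth, and the two independent oracles."""

from __future__ import annotations

import filecmp

import pytest

from adjforest import (
    AdjacencyRecord,
    CostModel,
    Event,
    min_forest_cost,
    compute_costs,
    run,
)
from adjforest.classes import cluster_adjacencies
from adjforest.reconcile import SpeciesIndex, validate_reconciled
from adjforest.simulate import (
    SimulationConfig,
    brute_force_min_cost,
    sankoff_binary,
    simulate,
    write_dataset,
)
from adjforest.trees import AdjForestError, TreeNode, read_species_tree


class TestSimulation:
    def test_same_seed_is_byte_identical(self, tmp_path):
        config = SimulationConfig(seed=13)
        write_dataset(simulate(config), tmp_path / "one")
        write_dataset(simulate(config), tmp_path / "two")
        for name in (
            "species.nwk", "gene_trees.nhx", "adjacencies.tsv",
            "truth_genomes.tsv", "truth_adjacencies.tsv", "truth_events.tsv",
        ):
            assert filecmp.cmp(
                tmp_path / "one" / name, tmp_path / "two" / name, shallow=False
            ), name

    def test_zero_rates_give_congruent_conserved_genomes(self):
        dataset = simulate(
            SimulationConfig(n_species=5, n_ancestral_genes=7, dup_rate=0,
                             loss_rate=0, rearrangement_rate=0, seed=2)
        )
        assert len(dataset.gene_trees) == 7
        for tree in dataset.gene_trees:
            events = {n.event for n in tree.postorder()}
            assert events <= {Event.SPEC, Event.EXTANT}
            assert sum(n.is_leaf for n in tree.postorder()) == 5
        # every genome carries the ancestral gene order
        lengths = {len(order) for order in dataset.truth.genomes.values()}
        assert lengths == {7}
        assert dataset.truth.total_cost_unit == 0

    def test_emitted_trees_satisfy_reconciled_properties(self):
        dataset = simulate(SimulationConfig(seed=4))
        index = SpeciesIndex(dataset.species_root)
        for tree in dataset.gene_trees:
            report = validate_reconciled(tree, index, check_lca=False)
            assert report.ok, report.violations

    def test_tandem_only_duplications_cost_nothing(self):
        for seed in range(8):
            dataset = simulate(
                SimulationConfig(n_species=6, n_ancestral_genes=12,
                                 dup_rate=0.2, loss_rate=0.0,
                                 rearrangement_rate=0.0, tandem_fraction=1.0,
                                 seed=seed)
            )
            result = run(
                dataset.species_root, dataset.gene_trees, dataset.adjacencies,
                trust_annotations=True,
            )
            assert result.summary["total_cost"] == 0

    def test_true_scenario_bounds_parsimony_from_above(self):
        for seed in range(12):
            dataset = simulate(SimulationConfig(seed=seed))
            result = run(
                dataset.species_root, dataset.gene_trees, dataset.adjacencies,
                trust_annotations=True,
            )
            assert result.summary["total_cost"] <= dataset.truth.total_cost_unit

    def test_invalid_config_rejected(self):
        with pytest.raises(AdjForestError):
            SimulationConfig(dup_rate=-0.1)
        with pytest.raises(AdjForestError):
            SimulationConfig(tandem_fraction=1.5)


class TestBruteForceOracle:
    def test_worked_example_class(self, worked_example):
        species, gene_trees, adjacencies = worked_example
        result = run(species, gene_trees, adjacencies)
        (cls,) = result.classes
        assert brute_force_min_cost(cls, CostModel()) == 1

    def test_extant_only_instance(self, tmp_path):
        from adjforest.trees import read_gene_trees

        (tmp_path / "s.nwk").write_text("(A,B)AB;\n")
        (tmp_path / "g.nwk").write_text("A|g1;\nA|g2;\n")
        species = read_species_tree(tmp_path / "s.nwk")
        trees = read_gene_trees(tmp_path / "g.nwk")
        result = run(species, trees, [AdjacencyRecord("g1", "g2")])
        (cls,) = result.classes
        assert brute_force_min_cost(cls, CostModel()) == 0
        assert result.summary["total_cost"] == 0

    def test_two_species_one_adjacency(self, tmp_path):
        from adjforest.trees import read_gene_trees

        (tmp_path / "s.nwk").write_text("(A,B)AB;\n")
        (tmp_path / "g.nwk").write_text("(A|g1,B|g2);\n(A|g3,B|g4);\n")
        species = read_species_tree(tmp_path / "s.nwk")
        trees = read_gene_trees(tmp_path / "g.nwk")
        result = run(species, trees, [AdjacencyRecord("g1", "g3")])
        assert result.summary["total_cost"] == 1

    def test_refuses_large_instances(self):
        dataset = simulate(SimulationConfig(n_species=8,
                                            n_ancestral_genes=10, seed=1,
                                            dup_rate=0, loss_rate=0,
                                            rearrangement_rate=0))
        index = SpeciesIndex(dataset.species_root)
        classes = cluster_adjacencies(
            dataset.adjacencies, dataset.gene_trees, index
        )
        big = max(classes, key=lambda c: len(list(c.tree1_root.postorder())))
        with pytest.raises(AdjForestError, match="exceed"):
            brute_force_min_cost(big, CostModel(), max_pairs=4)

    def test_agrees_with_dp_on_random_instances(self):
        model = CostModel()
        checked = 0
        for seed in range(25):
            cfg = SimulationConfig(n_species=3, n_ancestral_genes=4,
                                   dup_rate=0.15, loss_rate=0.15,
                                   rearrangement_rate=0.2, seed=seed)
            dataset = simulate(cfg)
            result = run(dataset.species_root, dataset.gene_trees,
                         dataset.adjacencies, model, trust_annotations=True)
            for cls, table in zip(result.classes, result.tables):
                if table.n_pairs <= 12:
                    assert (
                        brute_force_min_cost(cls, model)
                        == min_forest_cost(table)
                    )
                    checked += 1
        assert checked >= 50


class TestSankoffOracle:
    @pytest.fixture
    def caterpillar(self, tmp_path):
        p = tmp_path / "s.nwk"
        p.write_text("(((A,B),C),D);\n")
        return read_species_tree(p)

    def test_all_present_costs_nothing(self, caterpillar):
        states = {s: 1 for s in "ABCD"}
        assert sankoff_binary(caterpillar, states, CostModel()) == 0

    def test_present_in_one_of_two_species(self, tmp_path):
        p = tmp_path / "s.nwk"
        p.write_text("(A,B)AB;\n")
        species = read_species_tree(p)
        assert sankoff_binary(species, {"A": 1}, CostModel()) == 1

    def test_alternating_presence_on_caterpillar(self, caterpillar):
        # brute-force over internal states gives 2 for presence in A and C
        states = {"A": 1, "B": 0, "C": 1, "D": 0}
        assert sankoff_binary(caterpillar, states, CostModel()) == 2

    def test_duplication_free_runs_reduce_to_sankoff(self):
        model = CostModel()
        for seed in range(15):
            dataset = simulate(
                SimulationConfig(n_species=6, n_ancestral_genes=10,
                                 dup_rate=0, loss_rate=0,
                                 rearrangement_rate=0.15, seed=seed)
            )
            result = run(dataset.species_root, dataset.gene_trees,
                         dataset.adjacencies, model)
            index = SpeciesIndex(dataset.species_root)
            total = 0
            for cls in result.classes:
                present = {a.species for a, _ in cls.adjacencies}
                total += sankoff_binary(
                    index.node_of[cls.tree1_root.species],
                    {sp: 1 for sp in present},
                    model,
                )
            assert total == result.summary["total_cost"]
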