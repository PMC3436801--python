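"""Ancestral-genome summaries: degrees, branch ratios, segment sizes."""

from __future__ import annotations

import pytest

from adjforest import (
    CostModel,
    Event,
    InputError,
    run,
)
from adjforest.core import AdjacencyForest, AdjacencyTree, AdjNode
from adjforest.simulate import SimulationConfig, simulate
from adjforest.stats import (
    adjacency_precision_recall,
    ancestral_genomes,
    degree_distribution,
    duplication_branch_lengths,
    gene_degrees,
    mean_segment_size,
)
from adjforest.trees import TreeNode


def _leaf_forest(pairs, species="X"):
    """Forest of bare Extant leaves, one per adjacency pair."""
    forest = AdjacencyForest()
    for k, (a, b) in enumerate(pairs):
        node = AdjNode(id=f"n{k}", event=Event.EXTANT, species=species,
                       pair=(a, b))
        forest.trees.append(AdjacencyTree(root=node))
    return forest


def _single_gene_trees(genes, species="X"):
    return [TreeNode(g, Event.EXTANT, species, gene=g) for g in genes]


class TestDegrees:
    def test_linear_three_gene_genome(self):
        forest = _leaf_forest([("a", "b"), ("b", "c")])
        trees = _single_gene_trees(["a", "b", "c"])
        degrees = gene_degrees(forest, trees)
        assert degrees == {"X": {"a": 1, "b": 2, "c": 1}}
        assert degree_distribution(degrees) == {1: 2 / 3, 2: 1 / 3}

    def test_gene_outside_all_adjacencies_has_degree_zero(self):
        forest = _leaf_forest([("a", "b")])
        trees = _single_gene_trees(["a", "b", "lonely"])
        assert gene_degrees(forest, trees)["X"]["lonely"] == 0

    def test_degree_sum_is_twice_adjacency_count(self):
        dataset = simulate(SimulationConfig(seed=9))
        result = run(dataset.species_root, dataset.gene_trees,
                     dataset.adjacencies)
        genomes = ancestral_genomes(result.forest, result.gene_trees)
        degrees = gene_degrees(result.forest, result.gene_trees)
        for species, table in degrees.items():
            assert sum(table.values()) == 2 * len(genomes[species].adjacencies)

    def test_conflict_shows_up_as_degree_above_two(self):
        forest = _leaf_forest(
            [("hub", "a"), ("hub", "b"), ("hub", "c"), ("hub", "d")]
        )
        trees = _single_gene_trees(["hub", "a", "b", "c", "d"])
        dist = degree_distribution(gene_degrees(forest, trees))
        assert dist[4] == pytest.approx(1 / 5)

    def test_empty_input_gives_empty_distribution(self):
        assert degree_distribution({}) == {}


def _segmental_fixture(n_segments, segment_sizes, species="anc1",
                       leaf_species="A"):
    """Gene trees with GDup nodes at `species` chained by ADup forest nodes.

    Each segment of size k contributes k duplicated gene-tree nodes and
    k - 1 ADup forest nodes; the surviving copies live in `leaf_species`.
    """
    trees = []
    forest = AdjacencyForest()
    counter = iter(range(10_000))
    for size in segment_sizes:
        dups = []
        for _ in range(size):
            k = next(counter)
            dup = TreeNode(f"d{k}", Event.GDUP, species)
            for side in "ab":
                leaf = TreeNode(f"d{k}{side}", Event.EXTANT, leaf_species,
                                gene=f"d{k}{side}")
                dup.add_child(leaf)
            trees.append(dup)
            dups.append(dup)
        for left, right in zip(dups, dups[1:]):
            node = AdjNode(id=f"A{next(counter)}", event=Event.ADUP,
                           species=species, pair=(left.id, right.id))
            for child_pair in ((0, 0), (1, 1)):
                node.add_child(
                    AdjNode(id=f"A{next(counter)}", event=Event.EXTANT,
                            species=species,
                            pair=(left.children[child_pair[0]].id,
                                  right.children[child_pair[1]].id))
                )
            forest.trees.append(AdjacencyTree(root=node))
    return forest, trees


class TestSegmentalDuplications:
    def test_isolated_duplications_mean_one(self):
        forest, trees = _segmental_fixture(5, [1] * 5)
        assert mean_segment_size(forest, trees)["anc1"] == 1.0

    def test_three_gene_segment(self):
        forest, trees = _segmental_fixture(1, [3])
        assert mean_segment_size(forest, trees)["anc1"] == 3.0

    def test_two_two_gene_segments(self):
        forest, trees = _segmental_fixture(2, [2, 2])
        assert mean_segment_size(forest, trees)["anc1"] == 2.0

    def test_inconsistent_counts_rejected(self):
        forest, trees = _segmental_fixture(1, [2])
        extra = AdjNode(id="bogus", event=Event.ADUP, species="anc1",
                        pair=("x", "y"))
        forest.trees.append(AdjacencyTree(root=extra))
        with pytest.raises(InputError):
            mean_segment_size(forest, trees)

    def test_branch_ratio_counts_adups_per_gene_node(self, tmp_path):
        from adjforest.trees import read_species_tree

        (tmp_path / "s.nwk").write_text("(A,B)anc1;\n")
        species_root = read_species_tree(tmp_path / "s.nwk")
        forest, trees = _segmental_fixture(1, [3])
        # 2 ADup nodes at anc1; gene-tree nodes at anc1: 3 GDup nodes
        ratios = duplication_branch_lengths(forest, trees, species_root)
        assert ratios["anc1"] == pytest.approx(2 / 3)
        assert ratios["A"] == 0.0  # genes there, but no adjacency dups
        assert ratios["B"] is None  # no genes mapped there: flagged missing

    def test_no_adups_means_all_zero_ratios(self, tmp_path):
        from adjforest.trees import read_species_tree

        (tmp_path / "s.nwk").write_text("(A,B)anc1;\n")
        species_root = read_species_tree(tmp_path / "s.nwk")
        forest = _leaf_forest([("a", "b")], species="A")
        trees = _single_gene_trees(["a", "b"], species="A")
        ratios = duplication_branch_lengths(forest, trees, species_root)
        assert ratios["A"] == 0.0


class TestAccuracy:
    def test_beats_gain_everything_at_leaves_baseline(self):
        # the naive alternative gains every adjacency at the leaves and
        # reconstructs no ancestral adjacency at all
        ours_r, ours_p = [], []
        for seed in range(4):
            dataset = simulate(
                SimulationConfig(n_species=6, n_ancestral_genes=15,
                                 dup_rate=0.03, loss_rate=0.03,
                                 rearrangement_rate=0.03, seed=seed)
            )
            result = run(dataset.species_root, dataset.gene_trees,
                         dataset.adjacencies, trust_annotations=True)
            extant = {l.species for l in dataset.species_root.leaves()}
            inferred = {
                sp: genome.adjacencies
                for sp, genome in ancestral_genomes(
                    result.forest, result.gene_trees
                ).items()
                if sp not in extant
            }
            truth = {
                sp: adj
                for sp, adj in dataset.truth.adjacencies.items()
                if sp not in extant
            }
            p, r = adjacency_precision_recall(inferred, truth)
            ours_p.append(p)
            ours_r.append(r)
            base_p, base_r = adjacency_precision_recall(
                {sp: set() for sp in truth}, truth
            )
            assert p > base_p and r > base_r
        assert min(ours_p) > 0.5 and min(ours_r) > 0.5
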