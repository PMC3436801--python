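"""Shared fixtures: the worked three-species example and small helpers.

The worked example: species tree (A,B)C; gene tree G1 = (a1, b1) rooted
at a speciation C5 in the ancestor C; gene tree G2 = ((a2, b2)C6,
(a3, b3)C7) rooted at a duplication C8 in C; extant adjacencies a1-a2,
b1-b2 and b1-b3. Its optimal adjacency forest has total cost 1: a cost-0
tree containing the ancestral adjacency (C5, C8) and a single-leaf tree
for the gained adjacency b1-b3.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from adjforest import (
    read_adjacencies,
    read_gene_trees,
    read_species_tree,
)

FIG_SPECIES = "(A,B)C;\n"
FIG_GENE_TREES = "(A|a1,B|b1)C5;\n((A|a2,B|b2)C6,(A|a3,B|b3)C7)C8;\n"
FIG_ADJACENCIES = "a1\ta2\nb1\tb2\nb1\tb3\n"


def write_worked_example(directory: Path) -> dict[str, Path]:
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": directory / "species.nwk",
        "gene_trees": directory / "gene_trees.nwk",
        "adjacencies": directory / "adjacencies.tsv",
    }
    paths["species"].write_text(FIG_SPECIES)
    paths["gene_trees"].write_text(FIG_GENE_TREES)
    paths["adjacencies"].write_text(FIG_ADJACENCIES)
    return paths


@pytest.fixture
def worked_example_paths(tmp_path):
    return write_worked_example(tmp_path / "fig")


@pytest.fixture
def worked_example(worked_example_paths):
    return (
        read_species_tree(worked_example_paths["species"]),
        read_gene_trees(worked_example_paths["gene_trees"]),
        read_adjacencies(worked_example_paths["adjacencies"]),
    )
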