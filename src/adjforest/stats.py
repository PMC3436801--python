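"""Ancestral-genome summaries derived from an adjacency forest.

An adjacency-forest node with event Extant, Spec, GDup or ADup asserts
that an adjacency was present, in its species, between its two gene-tree
nodes; collecting these per species gives ancestral gene orders (as
adjacency sets).  From them we derive gene degrees and their distribution
(degree 2 is the signature of linear chromosomes; degree > 2 flags
conflicts), the per-branch density of adjacency duplications (pairs of
genes duplicated together, i.e. segmental duplications), and the mean
size of duplicated segments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .core import AdjacencyForest
from .trees import Event, InputError, TreeNode

__all__ = [
    "AncestralGenome",
    "ancestral_genomes",
    "gene_degrees",
    "degree_distribution",
    "duplication_branch_lengths",
    "mean_segment_size",
    "adjacency_precision_recall",
    "degrees_table",
    "branch_lengths_table",
]

#: forest events that assert a present adjacency in their species
PRESENCE_EVENTS = {Event.EXTANT, Event.SPEC, Event.GDUP, Event.ADUP}


@dataclass
class AncestralGenome:
    """Gene content and adjacency set of one (ancestral or extant) species."""

    species: str
    genes: Set[str] = field(default_factory=set)
    adjacencies: Set[Tuple[str, str]] = field(default_factory=set)


def _gene_node_ids(gene_trees: Sequence[TreeNode]) -> Dict[str, Set[str]]:
    """Per species, ids of gene-tree nodes present there (losses excluded)."""
    genes: Dict[str, Set[str]] = {}
    for root in gene_trees:
        for node in root.postorder():
            if node.event is Event.GLOS:
                continue
            genes.setdefault(node.species, set()).add(node.id)
    return genes


def ancestral_genomes(
    forest: AdjacencyForest, gene_trees: Sequence[TreeNode]
) -> Dict[str, AncestralGenome]:
    """Assemble per-species genomes from gene trees and forest nodes."""
    genomes = {
        species: AncestralGenome(species=species, genes=ids)
        for species, ids in _gene_node_ids(gene_trees).items()
    }
    for node in forest.nodes():
        if node.event in PRESENCE_EVENTS and node.pair is not None:
            pair = tuple(sorted(node.pair))
            genomes[node.species].adjacencies.add(pair)
    return genomes


def gene_degrees(
    forest: AdjacencyForest, gene_trees: Sequence[TreeNode]
) -> Dict[str, Dict[str, int]]:
    """Per species, the number of adjacencies each gene takes part in.

    Genes in no adjacency get degree 0; the per-species degree sum equals
    twice the number of adjacencies of that species.
    """
    degrees: Dict[str, Dict[str, int]] = {}
    for species, genome in ancestral_genomes(forest, gene_trees).items():
        table = {gene: 0 for gene in genome.genes}
        for a, b in genome.adjacencies:
            table[a] += 1
            table[b] += 1
        degrees[species] = table
    return degrees


def degree_distribution(
    degrees: Dict[str, Dict[str, int]],
    ancestral_only: bool = False,
    species_root: Optional[TreeNode] = None,
) -> Dict[int, float]:
    """Normalized histogram of gene degrees (proportions summing to 1).

    With ``ancestral_only`` the extant species (leaves of ``species_root``)
    are excluded, mirroring summaries of reconstructed genomes.
    """
    if ancestral_only:
        if species_root is None:
            raise InputError("ancestral_only requires the species tree")
        extant = {leaf.species for leaf in species_root.leaves()}
        pools = [t for s, t in degrees.items() if s not in extant]
    else:
        pools = list(degrees.values())
    counts = Counter(d for table in pools for d in table.values())
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: counts[k] / total for k in sorted(counts)}


def duplication_branch_lengths(
    forest: AdjacencyForest,
    gene_trees: Sequence[TreeNode],
    species_root: TreeNode,
) -> Dict[str, Optional[float]]:
    """Per species-tree branch (keyed by its lower node), the number of
    adjacency duplications over the number of gene-tree nodes assigned to
    that species; ``None`` for branches with no genes at all."""
    adups = Counter(
        node.species for node in forest.nodes() if node.event is Event.ADUP
    )
    genes = _gene_node_ids(gene_trees)
    ratios: Dict[str, Optional[float]] = {}
    for snode in species_root.preorder():
        n_genes = len(genes.get(snode.species, ()))
        if n_genes == 0:
            ratios[snode.species] = None
        else:
            ratios[snode.species] = adups.get(snode.species, 0) / n_genes
    return ratios


def mean_segment_size(
    forest: AdjacencyForest,
    gene_trees: Sequence[TreeNode],
    species: Optional[str] = None,
) -> Dict[str, Optional[float]]:
    """Mean size of duplicated segments per species.

    A duplicated segment of *k* genes shows up as *k* gene duplications
    chained by *k - 1* adjacency duplications, so with ``D_g`` gene
    duplications and ``D_a`` adjacency duplications at a species the mean
    segment size is ``D_g / (D_g - D_a)``; 1.0 when no adjacency
    duplication occurred, ``None`` (undefined) when ``D_g`` is 0.
    """
    gdups = Counter(
        node.species
        for root in gene_trees
        for node in root.postorder()
        if node.event is Event.GDUP
    )
    adups = Counter(
        node.species for node in forest.nodes() if node.event is Event.ADUP
    )
    targets = [species] if species is not None else sorted(
        set(gdups) | set(adups)
    )
    out: Dict[str, Optional[float]] = {}
    for sp in targets:
        d_g, d_a = gdups.get(sp, 0), adups.get(sp, 0)
        if d_g == 0:
            if d_a > 0:
                raise InputError(
                    f"species {sp!r}: {d_a} adjacency duplications but no "
                    "gene duplications"
                )
            out[sp] = None
        elif d_a >= d_g:
            raise InputError(
                f"species {sp!r}: D_a={d_a} >= D_g={d_g} (a k-gene segment "
                "has k-1 adjacency duplications)"
            )
        else:
            out[sp] = d_g / (d_g - d_a)
    return out


def adjacency_precision_recall(
    inferred: Dict[str, Set[Tuple[str, str]]],
    truth: Dict[str, Set[Tuple[str, str]]],
) -> Tuple[float, float]:
    """Micro-averaged precision/recall of ancestral adjacencies.

    Both inputs map species to sets of unordered gene-node id pairs;
    species present in only one input count with empty sets on the other
    side. An empty prediction has precision 0; empty truth gives recall 1.
    """
    tp = fp = fn = 0
    for sp in set(inferred) | set(truth):
        inf = {tuple(sorted(p)) for p in inferred.get(sp, set())}
        tru = {tuple(sorted(p)) for p in truth.get(sp, set())}
        tp += len(inf & tru)
        fp += len(inf - tru)
        fn += len(tru - inf)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------

def degrees_table(degrees: Dict[str, Dict[str, int]]) -> pd.DataFrame:
    rows = [
        {"species": sp, "gene_node": g, "degree": d}
        for sp in sorted(degrees)
        for g, d in sorted(degrees[sp].items())
    ]
    return pd.DataFrame(rows, columns=["species", "gene_node", "degree"])


def branch_lengths_table(ratios: Dict[str, Optional[float]]) -> pd.DataFrame:
    rows = [
        {
            "species": sp,
            "adup_per_gene": "" if ratio is None else ratio,
            "status": "missing" if ratio is None else "ok",
        }
        for sp, ratio in ratios.items()
    ]
    return pd.DataFrame(rows, columns=["species", "adup_per_gene", "status"])
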