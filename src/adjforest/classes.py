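"""Equivalence classes of extant adjacencies.

Two adjacencies can share an ancestor only when their extremities live in
the same (ordered) pair of gene trees under species-matched ancestors, or,
within a single tree, when both adjacencies stem from the same duplication
node.  Classes are the connected components of that relation and are
processed independently by the dynamic program.

Each class is reduced to a pair of rooted subtrees: for a same-tree class
the two subtrees hang from the children of the shared duplication node;
in all cases the class is then rooted at the highest species-matched
ancestor pair of its extremities, where the root adjacency gain is free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx

from .reconcile import SpeciesIndex
from .trees import AdjacencyRecord, Event, InputError, TreeNode

__all__ = [
    "AdjacencyClass",
    "cluster_adjacencies",
    "split_same_tree_class",
    "restrict_to_class_roots",
]


@dataclass
class AdjacencyClass:
    """A class of extant adjacencies with its two species-matched subtrees.

    ``adjacencies`` holds oriented leaf pairs: the first leaf of each pair
    lies in ``tree1_root``'s subtree, the second in ``tree2_root``'s.
    """

    adjacencies: List[Tuple[TreeNode, TreeNode]]
    tree1_root: TreeNode
    tree2_root: TreeNode
    records: List[AdjacencyRecord] = field(default_factory=list)
    class_id: int = -1

    @property
    def leaf_pairs(self) -> List[Tuple[str, str]]:
        return [(a.gene, b.gene) for a, b in self.adjacencies]


def _tree_lca(a: TreeNode, b: TreeNode) -> TreeNode:
    anc_a = [a] + list(a.ancestors())
    depth = {id(n): i for i, n in enumerate(anc_a)}
    node = b
    while id(node) not in depth:
        node = node.parent
        if node is None:
            raise InputError("nodes are not in the same tree")
    return node


def _species_chain(node: TreeNode) -> List[str]:
    """Species along the root path of ``node`` (deduplicated, bottom-up)."""
    chain: List[str] = []
    for n in node.ancestors(include_self=True):
        if not chain or chain[-1] != n.species:
            chain.append(n.species)
    return chain


def cluster_adjacencies(
    adjacencies: Sequence[AdjacencyRecord],
    gene_trees: Sequence[TreeNode],
    species_index: SpeciesIndex,
) -> List[AdjacencyClass]:
    """Partition extant adjacencies into equivalence classes.

    Cross-tree adjacencies between the same unordered tree pair are related
    when species-matched ancestors dominating the respective extremities
    exist; same-tree adjacencies are related when they share their
    extremities' LCA (which must be a duplication node). Components are
    computed with networkx; classes come out in deterministic sorted order.
    """
    leaf_of: Dict[str, TreeNode] = {}
    tree_index: Dict[str, int] = {}
    for t_i, root in enumerate(gene_trees):
        for leaf in root.leaves():
            if leaf.gene is not None:
                leaf_of[leaf.gene] = leaf
                tree_index[leaf.gene] = t_i

    same_tree: Dict[Tuple[int, int], List[AdjacencyRecord]] = {}
    cross_tree: Dict[Tuple[int, int], List[AdjacencyRecord]] = {}
    lca_nodes: Dict[Tuple[int, int], TreeNode] = {}
    node_ids: Dict[int, Dict[TreeNode, int]] = {}
    for t_i, root in enumerate(gene_trees):
        node_ids[t_i] = {n: k for k, n in enumerate(root.postorder())}

    for record in adjacencies:
        ga, gb = record.genes
        if ga not in leaf_of or gb not in leaf_of:
            missing = [g for g in record.genes if g not in leaf_of]
            raise InputError(f"adjacency {record}: unknown gene(s) {missing}")
        ta, tb = tree_index[ga], tree_index[gb]
        if ta == tb:
            lca = _tree_lca(leaf_of[ga], leaf_of[gb])
            if lca.event is not Event.GDUP:
                raise InputError(
                    f"adjacency {record}: within-tree extremities whose LCA "
                    f"{lca.id!r} is a {lca.event.value}, not a duplication"
                )
            key = (ta, node_ids[ta][lca])
            same_tree.setdefault(key, []).append(record)
            lca_nodes[key] = lca
        else:
            key = (min(ta, tb), max(ta, tb))
            cross_tree.setdefault(key, []).append(record)

    classes: List[AdjacencyClass] = []

    # Same-tree classes: the shared-LCA condition *is* the relation.
    for key in sorted(same_tree):
        classes.append(
            split_same_tree_class(same_tree[key], lca_nodes[key], leaf_of)
        )

    # Cross-tree classes: connected components of the species-matched
    # dominating-ancestor relation within each tree pair.
    for (t1, t2) in sorted(cross_tree):
        records = cross_tree[(t1, t2)]
        oriented = []
        for record in records:
            ga, gb = record.genes
            if tree_index[ga] == t1:
                oriented.append((leaf_of[ga], leaf_of[gb]))
            else:
                oriented.append((leaf_of[gb], leaf_of[ga]))
        graph = nx.Graph()
        graph.add_nodes_from(range(len(records)))
        chains = [
            (set(_species_chain(a)), set(_species_chain(b))) for a, b in oriented
        ]
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                lca1 = _tree_lca(oriented[i][0], oriented[j][0])
                lca2 = _tree_lca(oriented[i][1], oriented[j][1])
                if set(_species_chain(lca1)) & set(_species_chain(lca2)):
                    graph.add_edge(i, j)
        for component in sorted(nx.connected_components(graph), key=min):
            members = sorted(component)
            classes.append(
                AdjacencyClass(
                    adjacencies=[oriented[i] for i in members],
                    tree1_root=gene_trees[t1],
                    tree2_root=gene_trees[t2],
                    records=[records[i] for i in members],
                )
            )

    for k, cls in enumerate(classes):
        cls.class_id = k
        restrict_to_class_roots(cls, species_index)
    return classes


def split_same_tree_class(
    records: Sequence[AdjacencyRecord],
    dup_node: TreeNode,
    leaf_of: Dict[str, TreeNode],
) -> AdjacencyClass:
    """Split a same-tree class at its duplication node.

    The two subtrees hanging from the duplication node's children become
    the class's tree pair; each adjacency is oriented with its first
    extremity under the first child.
    """
    child1, child2 = dup_node.children
    under1 = {id(n) for n in child1.postorder()}
    oriented: List[Tuple[TreeNode, TreeNode]] = []
    for record in records:
        la, lb = leaf_of[record.gene_a], leaf_of[record.gene_b]
        a_in_1 = id(la) in under1
        b_in_1 = id(lb) in under1
        if a_in_1 == b_in_1:
            raise InputError(
                f"adjacency {record}: both extremities under the same child "
                f"of duplication node {dup_node.id!r}"
            )
        oriented.append((la, lb) if a_in_1 else (lb, la))
    return AdjacencyClass(
        adjacencies=oriented,
        tree1_root=child1,
        tree2_root=child2,
        records=list(records),
    )


def restrict_to_class_roots(
    cls: AdjacencyClass, species_index: SpeciesIndex
) -> AdjacencyClass:
    """Root the class at its highest species-matched ancestor pair.

    Each side's extremity LCA is raised, in lockstep and without leaving
    the class's tree pair, to the highest ancestor pair whose species
    match. At that pair the root-gain-is-free conditions provably hold:
    at least one side is a (sub)tree root, and the other is either a root
    too or hangs below a speciation into a different species. Raising any
    higher is impossible (no species match), so no ancestral-presence
    scenario is lost, and the domains of distinct classes of one tree
    pair never share a node pair. In place; returns the class.
    """
    cap1, cap2 = cls.tree1_root, cls.tree2_root
    depth = species_index.depth

    def side_lca(side: int) -> TreeNode:
        nodes = [pair[side] for pair in cls.adjacencies]
        lca = nodes[0]
        for node in nodes[1:]:
            lca = _tree_lca(lca, node)
        return lca

    def chain(node: TreeNode, cap: TreeNode) -> set:
        species = {node.species}
        while node is not cap:
            node = node.parent
            species.add(node.species)
        return species

    lca1, lca2 = side_lca(0), side_lca(1)
    common = chain(lca1, cap1) & chain(lca2, cap2)
    if not common:
        raise InputError(
            f"class {cls.class_id}: no species-matched ancestor pair"
        )
    top_depth = min(depth[s] for s in common)

    def raise_to_top(node: TreeNode, cap: TreeNode) -> TreeNode:
        while node is not cap and depth[node.parent.species] >= top_depth:
            node = node.parent
        return node

    r1 = raise_to_top(lca1, cap1)
    r2 = raise_to_top(lca2, cap2)
    if r1.species != r2.species:
        raise InputError(
            f"class {cls.class_id}: root species diverge after raising "
            f"({r1.species!r} vs {r2.species!r})"
        )
    cls.tree1_root, cls.tree2_root = r1, r2
    return cls
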