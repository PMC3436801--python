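"""LCA reconciliation of gene trees against a species tree.

A reconciled gene tree maps every node to a species (the lowest common
ancestor of its extant descendants' species), labels internal nodes as
speciations or gene duplications, and represents every gene loss as an
explicit ``GLos`` leaf, so that:

* a duplication node and both of its children map to the same species;
* a speciation node's two children map exactly to the two child species
  of the node's species.

The dynamic program in :mod:`adjforest.core` relies on these properties
holding exactly, which is why input trees are re-reconciled by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

from .trees import Event, InputError, TreeNode

__all__ = [
    "SpeciesIndex",
    "lca_map",
    "annotate_events",
    "insert_losses",
    "reconcile",
    "validate_reconciled",
    "ReconciliationReport",
    "count_losses",
]


class SpeciesIndex:
    """Constant-time-ish LCA and ancestry queries on a species tree."""

    def __init__(self, species_root: TreeNode) -> None:
        self.root = species_root
        self.node_of: Dict[str, TreeNode] = {}
        self.depth: Dict[str, int] = {}
        for node in species_root.preorder():
            if node.species in self.node_of:
                raise InputError(f"duplicate species label {node.species!r}")
            self.node_of[node.species] = node
            self.depth[node.species] = (
                0 if node.parent is None else self.depth[node.parent.species] + 1
            )

    def lca(self, a: str, b: str) -> str:
        na, nb = self.node_of[a], self.node_of[b]
        while self.depth[na.species] > self.depth[nb.species]:
            na = na.parent
        while self.depth[nb.species] > self.depth[na.species]:
            nb = nb.parent
        while na is not nb:
            na, nb = na.parent, nb.parent
        return na.species

    def is_ancestor_or_equal(self, anc: str, desc: str) -> bool:
        node = self.node_of[desc]
        while node is not None:
            if node.species == anc:
                return True
            node = node.parent
        return False

    def child_towards(self, anc: str, desc: str) -> TreeNode:
        """The child of ``anc`` on the path down to ``desc`` (desc < anc)."""
        for child in self.node_of[anc].children:
            if self.is_ancestor_or_equal(child.species, desc):
                return child
        raise InputError(f"{desc!r} is not a strict descendant of {anc!r}")


def lca_map(gene_tree: TreeNode, species_index: SpeciesIndex) -> Dict[TreeNode, str]:
    """Map every gene-tree node to the species-tree LCA of its extant
    descendants' species (one post-order pass)."""
    mapping: Dict[TreeNode, str] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            if node.species is None:
                raise InputError(f"leaf {node.id!r} has no species")
            if node.species not in species_index.node_of:
                raise InputError(
                    f"leaf {node.id!r}: species {node.species!r} absent from species tree"
                )
            mapping[node] = node.species
        else:
            species = mapping[node.children[0]]
            for child in node.children[1:]:
                species = species_index.lca(species, mapping[child])
            mapping[node] = species
    return mapping


def annotate_events(gene_tree: TreeNode, mapping: Dict[TreeNode, str]) -> TreeNode:
    """Label internal nodes GDup/Spec from the LCA mapping; leaves Extant.

    An internal node is a duplication exactly when it maps to the same
    species as at least one of its children.
    """
    for node in gene_tree.postorder():
        node.species = mapping[node]
        if node.is_leaf:
            if node.event is not Event.GLOS:
                node.event = Event.EXTANT
        else:
            if any(mapping[c] == mapping[node] for c in node.children):
                node.event = Event.GDUP
            else:
                node.event = Event.SPEC
    return gene_tree


def insert_losses(gene_tree: TreeNode, species_index: SpeciesIndex) -> TreeNode:
    """Insert Spec/GLos chains so the reconciled-tree invariants hold.

    For a speciation node at species *s* whose child maps strictly below
    the corresponding child species of *s*, and for a duplication node
    whose child maps strictly below *s*, a chain of speciation nodes with
    loss leaves is grafted along the species path. Idempotent. Speciation
    children are normalized to follow species-tree child order.
    """
    counter = itertools.count(1)

    def loss_leaf(species: str) -> TreeNode:
        return TreeNode(
            id=f"loss{next(counter)}_{species}", event=Event.GLOS, species=species
        )

    def extend(subtree: TreeNode, target_species: str) -> TreeNode:
        # Return a subtree whose root maps to target_species, grafting
        # Spec nodes with GLos siblings down to the subtree's species.
        if subtree.species == target_species:
            return subtree
        node = TreeNode(
            id=f"spec{next(counter)}_{target_species}",
            event=Event.SPEC,
            species=target_species,
        )
        on_path = species_index.child_towards(target_species, subtree.species)
        snode = species_index.node_of[target_species]
        for schild in snode.children:
            if schild is on_path:
                node.add_child(extend(subtree, schild.species))
            else:
                node.add_child(loss_leaf(schild.species))
        return node

    def complete(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return node
        done = [complete(c) for c in node.children]
        if node.event is Event.GDUP:
            new_children = [extend(c, node.species) for c in done]
        else:  # Spec
            snode = species_index.node_of[node.species]
            by_target: list[TreeNode] = []
            remaining = list(done)
            for schild in snode.children:
                match = next(
                    (
                        c
                        for c in remaining
                        if species_index.is_ancestor_or_equal(
                            schild.species, c.species
                        )
                    ),
                    None,
                )
                if match is None:
                    raise InputError(
                        f"speciation node {node.id!r}: no child maps under "
                        f"species {schild.species!r} (tree not LCA-annotated?)"
                    )
                remaining.remove(match)
                by_target.append(extend(match, schild.species))
            new_children = by_target
        node.children = []
        for child in new_children:
            node.add_child(child)
        return node

    root = complete(gene_tree)
    root.parent = None
    return root


def strip_losses(gene_tree: TreeNode) -> Optional[TreeNode]:
    """Remove GLos leaves and suppress the resulting unary nodes.

    Returns ``None`` when nothing extant remains. Used before
    re-reconciling an input tree that already carries loss leaves.
    """
    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            return None if node.event is Event.GLOS else node
        kept = [c for c in (prune(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = []
        for child in kept:
            node.add_child(child)
        return node

    root = prune(gene_tree)
    if root is not None:
        root.parent = None
    return root


def reconcile(gene_tree: TreeNode, species_index: SpeciesIndex) -> TreeNode:
    """Full LCA reconciliation: strip prior losses, map, annotate, insert.

    Operates in place and returns the (possibly new) root.
    """
    stripped = strip_losses(gene_tree)
    if stripped is None:
        raise InputError(f"gene tree {gene_tree.id!r} has no extant leaves")
    mapping = lca_map(stripped, species_index)
    annotate_events(stripped, mapping)
    return insert_losses(stripped, species_index)


def count_losses(gene_tree: TreeNode) -> int:
    return sum(1 for n in gene_tree.postorder() if n.event is Event.GLOS)


@dataclass
class ReconciliationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)


def validate_reconciled(
    gene_tree: TreeNode, species_index: SpeciesIndex, check_lca: bool = True
) -> ReconciliationReport:
    """Check the reconciled-gene-tree properties; report-only.

    The extant-descendant LCA clause is only checked when ``check_lca``
    is set, and then only for nodes both of whose children retain extant
    leaves: loss-chain nodes, and true event placements that a pure LCA
    mapping would move, carry no extant signal to check against. The
    local clauses (event domains, duplication children in the same
    species, speciation children on the two child species) are what the
    dynamic program actually relies on and are always enforced.
    """
    report = ReconciliationReport()
    extant_lca: Dict[TreeNode, Optional[str]] = {}
    for node in gene_tree.postorder():
        if node.species is None or node.event is None:
            report.add(f"node {node.id!r}: missing annotation")
            continue
        if node.is_leaf:
            if node.event not in (Event.EXTANT, Event.GLOS):
                report.add(f"leaf {node.id!r}: event {node.event.value} not allowed")
            extant_lca[node] = node.species if node.event is Event.EXTANT else None
            continue
        if node.event not in (Event.SPEC, Event.GDUP):
            report.add(f"internal {node.id!r}: event {node.event.value} not allowed")
            continue
        if len(node.children) != 2:
            report.add(f"internal {node.id!r}: {len(node.children)} children")
            continue
        c1, c2 = node.children
        if node.event is Event.GDUP:
            if not (c1.species == c2.species == node.species):
                report.add(
                    f"duplication {node.id!r}: children map to "
                    f"{c1.species!r}/{c2.species!r}, expected {node.species!r}"
                )
        else:
            snode = species_index.node_of.get(node.species)
            if snode is None or len(snode.children) != 2:
                report.add(
                    f"speciation {node.id!r}: species {node.species!r} "
                    "is not an internal species-tree node"
                )
            else:
                expected = {s.species for s in snode.children}
                if {c1.species, c2.species} != expected:
                    report.add(
                        f"speciation {node.id!r}: children map to "
                        f"{{{c1.species!r}, {c2.species!r}}}, expected species "
                        f"children {sorted(expected)!r}"
                    )
        subs = [extant_lca.get(c) for c in (c1, c2)]
        subs = [s for s in subs if s is not None]
        if subs:
            lca = subs[0]
            for s in subs[1:]:
                lca = species_index.lca(lca, s)
            extant_lca[node] = lca
            if check_lca and len(subs) == 2 and lca != node.species:
                report.add(
                    f"node {node.id!r}: species {node.species!r} differs from "
                    f"extant-descendant LCA {lca!r}"
                )
        else:
            extant_lca[node] = None
    return report
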