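"""Annotated phylogenetic trees and the plain-text formats around them.

Three kinds of rooted binary trees are handled: a species tree, reconciled
gene trees, and adjacency trees (the output of the dynamic program, see
:mod:`adjforest.core`).  Every node carries an event label and a species
label; extant gene-tree leaves additionally carry a gene identifier.

Formats: Newick (optionally with ``[&&NHX:...]`` tags ``Ev``, ``S``, ``A``)
for trees, parsed and written through dendropy; two-column whitespace- or
tab-separated text for adjacency lists and gene-to-species maps.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "Event",
    "TreeNode",
    "AdjacencyRecord",
    "AdjForestError",
    "FormatError",
    "InputError",
    "read_species_tree",
    "read_gene_trees",
    "read_gene_species_map",
    "read_adjacencies",
    "write_species_tree",
    "write_gene_trees",
    "write_adjacencies",
    "write_adjacency_forest",
    "read_adjacency_forest",
    "validate_inputs",
]


class AdjForestError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AdjForestError):
    """A file does not conform to the expected dialect."""


class InputError(AdjForestError):
    """Inputs are individually well-formed but mutually inconsistent."""


class Event(str, enum.Enum):
    """Evolutionary event labels carried by tree nodes.

    ``ALOS`` is the loss of an adjacency through the loss of both of its
    genes; ``BREAK`` is the loss of an adjacency through rearrangement.
    Only adjacency gains and breakages carry a cost in the objective.
    """

    EXTANT = "Extant"
    SPEC = "Spec"
    GDUP = "GDup"
    GLOS = "GLos"
    ADUP = "ADup"
    ALOS = "ALos"
    BREAK = "Break"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TreeNode:
    """A node of a rooted annotated tree (max two children).

    Attributes
    ----------
    id:
        Unique identifier within its tree (leaf label, internal Newick
        label, or a generated one).
    event:
        An :class:`Event` or ``None`` when not yet annotated.
    species:
        Species identifier, ``None`` when not yet assigned.
    gene:
        Gene identifier; set only on extant gene-tree leaves.
    """

    __slots__ = ("id", "children", "parent", "event", "species", "gene")

    def __init__(
        self,
        id: str,
        event: Optional[Event] = None,
        species: Optional[str] = None,
        gene: Optional[str] = None,
    ) -> None:
        self.id = id
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.event = event
        self.species = species
        self.gene = gene

    # -- structure ---------------------------------------------------------

    def add_child(self, child: "TreeNode") -> "TreeNode":
        if len(self.children) >= 2:
            raise FormatError(f"node {self.id!r} would have more than 2 children")
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def ancestors(self, include_self: bool = False) -> Iterator["TreeNode"]:
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        ev = self.event.value if self.event else "?"
        return f"<TreeNode {self.id} {ev}@{self.species}>"


@dataclass(frozen=True)
class AdjacencyRecord:
    """An unordered pair of distinct extant gene identifiers."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise FormatError(f"self-adjacency {self.gene_a!r}–{self.gene_b!r}")
        if self.gene_b < self.gene_a:  # canonical order => unordered equality
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def other(self, gene: str) -> str:
        if gene == self.gene_a:
            return self.gene_b
        if gene == self.gene_b:
            return self.gene_a
        raise KeyError(gene)

    def __str__(self) -> str:
        return f"{self.gene_a}--{self.gene_b}"


# ---------------------------------------------------------------------------
# Newick / NHX parsing
# ---------------------------------------------------------------------------

_NHX_PREFIX = "&&NHX"


def _parse_nhx(comments: Sequence[str]) -> dict[str, str]:
    tags: dict[str, str] = {}
    for comment in comments:
        if not comment.startswith(_NHX_PREFIX):
            continue
        for item in comment[len(_NHX_PREFIX):].split(":"):
            if "=" in item:
                key, value = item.split("=", 1)
                tags[key] = value
    return tags


def _format_nhx(tags: Mapping[str, str]) -> str:
    return _NHX_PREFIX + "".join(f":{k}={v}" for k, v in tags.items())


def _node_label(nd: dendropy.Node) -> Optional[str]:
    if nd.taxon is not None and nd.taxon.label is not None:
        return nd.taxon.label
    return nd.label


def _from_dendropy(dtree: dendropy.Tree) -> tuple[TreeNode, dict[TreeNode, dict[str, str]]]:
    """Convert a dendropy tree to a TreeNode tree, keeping NHX tags aside."""
    tags: dict[TreeNode, dict[str, str]] = {}

    def build(dnode: dendropy.Node, extra_comments: Sequence[str] = ()) -> TreeNode:
        if len(dnode.child_nodes()) > 2:
            raise FormatError(
                f"non-binary node {(_node_label(dnode) or '<unnamed>')!r}: "
                f"{len(dnode.child_nodes())} children"
            )
        node = TreeNode(id=_node_label(dnode) or "")
        tags[node] = _parse_nhx(list(dnode.comments) + list(extra_comments))
        for dchild in dnode.child_nodes():
            node.add_child(build(dchild))
        return node

    # dendropy hangs a single-leaf tree's trailing comment on the tree itself
    return build(dtree.seed_node, dtree.comments), tags


def _parse_newick_file(path: str | Path) -> list[tuple[TreeNode, dict[TreeNode, dict[str, str]]]]:
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            extract_comment_metadata=False,
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except FormatError:
        raise
    except Exception as exc:  # dendropy raises reader-specific classes
        raise FormatError(f"{path}: {exc}") from exc
    return [_from_dendropy(t) for t in trees]


def _to_dendropy(root: TreeNode, leaf_label, node_tags) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)

    def fill(node: TreeNode, dnode: dendropy.Node) -> None:
        if node.is_leaf:
            dnode.taxon = tns.new_taxon(leaf_label(node))
        else:
            dnode.label = node.id
        tags = node_tags(node)
        if tags:
            dnode.comments.append(_format_nhx(tags))
        for child in node.children:
            fill(child, dnode.new_child())

    fill(root, dtree.seed_node)
    return dtree


def _newick_string(root: TreeNode, leaf_label, node_tags) -> str:
    dtree = _to_dendropy(root, leaf_label, node_tags)
    return dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_item_comments=False,
        unquoted_underscores=True,
    ).strip()


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def read_species_tree(path: str | Path) -> TreeNode:
    """Read a rooted binary species tree from a Newick file.

    Leaves become ``Extant`` nodes and internal nodes ``Spec`` nodes;
    unlabeled internal nodes are assigned deterministic post-order names
    ``anc1, anc2, ...`` so outputs are reproducible.
    """
    parsed = _parse_newick_file(path)
    if len(parsed) != 1:
        raise FormatError(f"expected exactly one species tree in {path}, found {len(parsed)}")
    root, _ = parsed[0]
    seen: set[str] = set()
    counter = itertools.count(1)
    for node in root.postorder():
        if node.is_leaf:
            if not node.id:
                raise FormatError("species tree has an unlabeled leaf")
            node.event = Event.EXTANT
        else:
            if len(node.children) != 2:
                raise FormatError(
                    f"species tree node {node.id or '<unnamed>'!r} is not binary"
                )
            node.event = Event.SPEC
            if not node.id:
                node.id = f"anc{next(counter)}"
        if node.id in seen:
            raise FormatError(f"duplicate species label {node.id!r}")
        seen.add(node.id)
        node.species = node.id
    return root


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

def read_gene_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``gene<TAB>species`` map."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        gene, species = fields
        if gene in mapping and mapping[gene] != species:
            raise FormatError(f"{path}:{lineno}: gene {gene!r} mapped to two species")
        mapping[gene] = species
    return mapping


def read_gene_trees(
    path: str | Path,
    species_map: Optional[Mapping[str, str]] = None,
) -> list[TreeNode]:
    """Read one or more gene trees from a Newick/NHX file.

    Each leaf must resolve to a species: either via ``species_map`` (gene id
    -> species) or via the default ``SPECIES|GENE`` leaf-label convention.
    NHX ``Ev``/``S`` tags, when present, are stored on the nodes; by default
    the pipeline re-reconciles anyway (see :mod:`adjforest.reconcile`).
    """
    trees: list[TreeNode] = []
    genes_seen: set[str] = set()
    for tree_index, (root, tags) in enumerate(_parse_newick_file(path)):
        counter = itertools.count(1)
        for node in root.postorder():
            node_tags = tags.get(node, {})
            if "S" in node_tags:
                node.species = node_tags["S"]
            if "Ev" in node_tags:
                try:
                    node.event = Event(node_tags["Ev"])
                except ValueError:
                    raise FormatError(
                        f"{path}: unknown NHX event {node_tags['Ev']!r} on {node.id!r}"
                    ) from None
            if node.is_leaf:
                if node.event is Event.GLOS:
                    if node.species is None:
                        raise FormatError(
                            f"{path}: loss leaf {node.id!r} lacks an S= species tag"
                        )
                    continue
                label = node.id
                if species_map is not None and label in species_map:
                    node.species = species_map[label]
                    node.gene = label
                elif "|" in label:
                    species, gene = label.split("|", 1)
                    node.species = species
                    node.gene = gene
                else:
                    raise FormatError(
                        f"{path}: cannot resolve species of leaf {label!r} "
                        "(no map entry and no 'SPECIES|GENE' label)"
                    )
                node.event = Event.EXTANT
                if node.gene in genes_seen:
                    raise FormatError(
                        f"{path}: gene {node.gene!r} occurs in more than one tree/leaf"
                    )
                genes_seen.add(node.gene)
                node.id = node.gene  # node ids stay pipe-free for NHX A= tags
            else:
                if not node.id:
                    node.id = f"T{tree_index}.n{next(counter)}"
        trees.append(root)
    return trees


def write_species_tree(root: TreeNode, path: str | Path) -> None:
    """Write a species tree as Newick with internal labels preserved."""
    Path(path).write_text(
        _newick_string(root, lambda n: n.species, lambda n: {}) + "\n"
    )


def write_gene_trees(trees: Iterable[TreeNode], path: str | Path) -> None:
    """Write gene trees as one NHX-annotated Newick string per line."""
    lines = []
    for root in trees:
        lines.append(_newick_string(root, _gene_leaf_label, _gene_node_tags))
    Path(path).write_text("\n".join(lines) + "\n")


def _gene_leaf_label(node: TreeNode) -> str:
    if node.event is Event.GLOS or node.gene is None:
        return node.id or f"loss_{node.species}"
    return f"{node.species}|{node.gene}"


def _gene_node_tags(node: TreeNode) -> dict[str, str]:
    tags: dict[str, str] = {}
    if node.event is not None:
        tags["Ev"] = node.event.value
    if node.species is not None:
        tags["S"] = node.species
    return tags


# ---------------------------------------------------------------------------
# Adjacency lists
# ---------------------------------------------------------------------------

def read_adjacencies(path: str | Path) -> list[AdjacencyRecord]:
    """Read a two-column adjacency list; '#' comments and blank lines ok.

    Pairs are unordered and deduplicated while preserving first-seen order.
    """
    records: list[AdjacencyRecord] = []
    seen: set[AdjacencyRecord] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        try:
            record = AdjacencyRecord(fields[0], fields[1])
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if record not in seen:
            seen.add(record)
            records.append(record)
    return records


def write_adjacencies(records: Iterable[AdjacencyRecord], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{r.gene_a}\t{r.gene_b}\n" for r in records)
    )


def validate_inputs(
    gene_trees: Sequence[TreeNode],
    adjacencies: Sequence[AdjacencyRecord],
) -> dict[str, TreeNode]:
    """Check every adjacency extremity is exactly one extant gene-tree leaf.

    Returns the gene-id -> leaf-node index. Raised errors name the genes.
    """
    leaf_of: dict[str, TreeNode] = {}
    for root in gene_trees:
        for leaf in root.leaves():
            if leaf.event is Event.GLOS or leaf.gene is None:
                continue
            if leaf.gene in leaf_of:
                raise InputError(f"gene {leaf.gene!r} occurs in more than one gene tree")
            leaf_of[leaf.gene] = leaf
    missing = sorted(
        {g for r in adjacencies for g in r.genes if g not in leaf_of}
    )
    if missing:
        raise InputError(
            "adjacency genes not found in any gene tree: " + ", ".join(missing)
        )
    return leaf_of


# ---------------------------------------------------------------------------
# Adjacency forests
# ---------------------------------------------------------------------------
# The forest container itself lives in adjforest.core; these functions only
# walk its (tree-shaped) nodes, so there is no import cycle on write.

def _adj_leaf_label(node) -> str:
    if node.event is Event.BREAK:
        return f"BREAK_{node.id}"
    return f"{node.pair[0]}|{node.pair[1]}"


def _adj_node_tags(node) -> dict[str, str]:
    tags = {"Ev": node.event.value, "S": node.species or ""}
    if node.pair is not None:
        tags["A"] = f"{node.pair[0]}|{node.pair[1]}"
    return tags


def write_adjacency_forest(forest, outdir: str | Path) -> None:
    """Write an adjacency forest to ``outdir``.

    Produces ``forest.nhx`` (one NHX Newick per adjacency tree),
    ``ancestral_adjacencies.tsv`` (species, gene_node_1, gene_node_2),
    ``events.tsv`` (tree_id, node_id, event, species) and ``summary.txt``.
    Round-trips through :func:`read_adjacency_forest`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lines = []
    events_rows = ["tree_id\tnode_id\tevent\tspecies"]
    adj_rows = ["species\tgene_node_1\tgene_node_2"]
    for tree_id, tree in enumerate(forest.trees):
        def tags_with_gain(node, _tree=tree):
            tags = _adj_node_tags(node)
            if node is _tree.root:
                tags["Gain"] = repr(_tree.gain)
            return tags

        lines.append(_newick_string(tree.root, _adj_leaf_label, tags_with_gain))
        for node in tree.root.postorder():
            events_rows.append(
                f"{tree_id}\t{node.id}\t{node.event.value}\t{node.species or ''}"
            )
            if node.pair is not None and node.event in (
                Event.EXTANT, Event.SPEC, Event.GDUP, Event.ADUP,
            ):
                adj_rows.append(f"{node.species}\t{node.pair[0]}\t{node.pair[1]}")
    (outdir / "forest.nhx").write_text("".join(l + "\n" for l in lines))
    (outdir / "events.tsv").write_text("".join(r + "\n" for r in events_rows))
    (outdir / "ancestral_adjacencies.tsv").write_text(
        "".join(r + "\n" for r in adj_rows)
    )
    (outdir / "summary.txt").write_text(
        f"gains={forest.n_gains} breaks={forest.n_breaks} cost={forest.cost}\n"
    )


def read_adjacency_forest(outdir: str | Path):
    """Read back a forest written by :func:`write_adjacency_forest`."""
    from .core import AdjacencyForest, AdjacencyTree, AdjNode

    outdir = Path(outdir)
    summary = (outdir / "summary.txt").read_text().split()
    fields = dict(item.split("=") for item in summary)
    trees = []
    counter = itertools.count()
    text = (outdir / "forest.nhx").read_text()
    for root_d, tags in _parse_newick_file_from_string(text):
        def build(node: TreeNode) -> AdjNode:
            t = tags.get(node, {})
            event = Event(t["Ev"])
            pair = tuple(t["A"].split("|", 1)) if "A" in t else None
            anode = AdjNode(
                id=f"F{next(counter)}",
                event=event,
                species=t.get("S") or None,
                pair=pair,
            )
            for child in node.children:
                anode.add_child(build(child))
            return anode

        gain = _parse_number(tags.get(root_d, {}).get("Gain", "0"))
        trees.append(AdjacencyTree(root=build(root_d), gain=gain))
    forest = AdjacencyForest(trees=trees)
    forest.n_gains = int(fields["gains"])
    forest.n_breaks = int(fields["breaks"])
    forest.cost = _parse_number(fields["cost"])
    return forest


def _parse_number(text: str):
    value = float(text)
    return int(value) if value.is_integer() else value


def _parse_newick_file_from_string(text: str):
    if not text.strip():
        return []
    try:
        trees = dendropy.TreeList.get(
            data=text,
            schema="newick",
            extract_comment_metadata=False,
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"adjacency forest: {exc}") from exc
    return [_from_dendropy(t) for t in trees]
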