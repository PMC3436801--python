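"""Minimum gain/breakage adjacency forests by dynamic programming.

For each adjacency class (a pair of species-matched reconciled subtrees
plus the extant adjacencies between them) the DP fills, in post-order over
species-matched node pairs ``(v1, v2)``, two values:

* ``c1(v1, v2)`` — minimum cost of an adjacency forest for the extant
  adjacencies between the two subtrees such that a forest node with
  ``A(N) = (v1, v2)`` exists (the ancestral adjacency is present);
* ``c0(v1, v2)`` — the same minimum with that node forbidden (absent).

Only adjacency gains and breakages are charged, at ``C(Gain)`` and
``C(Break)``; gene duplications and losses are free, and the adjacency at
the class root pair is a free gain (it corresponds to a gene-tree root
pair or to the two children of a duplication node, where the gain either
is tandem or may predate the subtree).

Backtracking from ``min(c0, c1)`` at the root pair materializes one
optimal forest; ties always prefer absence, which in the duplication-free
limit keeps ancestral genomes linear.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .classes import AdjacencyClass, cluster_adjacencies
from .reconcile import SpeciesIndex, reconcile, validate_reconciled
from .trees import (
    AdjacencyRecord,
    Event,
    InputError,
    TreeNode,
    validate_inputs,
)

__all__ = [
    "INF",
    "CostModel",
    "Cell",
    "CostTable",
    "AdjNode",
    "AdjacencyTree",
    "AdjacencyForest",
    "compute_costs",
    "min_forest_cost",
    "backtrack",
    "run",
    "RunResult",
    "validate_forest",
]

INF = float("inf")


@dataclass(frozen=True)
class CostModel:
    """Costs of the two charged events. Defaults: unit gain and breakage."""

    gain_cost: float = 1
    break_cost: float = 1

    def __post_init__(self) -> None:
        if not (self.gain_cost >= 0 and self.break_cost >= 0):
            raise InputError("gain and breakage costs must be finite and >= 0")


# ---------------------------------------------------------------------------
# Cost table
# ---------------------------------------------------------------------------

PairKey = Tuple[TreeNode, TreeNode]


@dataclass
class Choice:
    """The decomposition chosen for one DP cell/state (a back-pointer).

    ``event``     event of the node created (``None`` for state 0);
    ``attach``    child pairs joined by an edge (present, state 1);
    ``breaks``    species of the Break leaf children created;
    ``spawn``     child pairs that start new adjacency trees, each charged
                  one ``C(Gain)``;
    ``recurse0``  child pairs resolved as absent (no edge, no node).
    """

    event: Optional[Event] = None
    attach: List[PairKey] = field(default_factory=list)
    breaks: List[str] = field(default_factory=list)
    spawn: List[PairKey] = field(default_factory=list)
    recurse0: List[PairKey] = field(default_factory=list)

    @property
    def presence_rank(self) -> int:
        # tie-break: prefer decompositions using fewer present pairs
        return len(self.attach) + len(self.spawn)


@dataclass
class Cell:
    c0: float
    c1: float
    bp0: Optional[Choice]
    bp1: Optional[Choice]
    case: str


@dataclass
class CostTable:
    cells: Dict[PairKey, Cell]
    root_pair: PairKey

    @property
    def n_pairs(self) -> int:
        return len(self.cells)

    def cell(self, v1: TreeNode, v2: TreeNode) -> Cell:
        return self.cells[(v1, v2)]

    def lookup(self, id1: str, id2: str) -> Cell:
        """Find a cell by node identifiers (order-insensitive)."""
        for (n1, n2), cell in self.cells.items():
            if (n1.id, n2.id) == (id1, id2) or (n1.id, n2.id) == (id2, id1):
                return cell
        raise KeyError((id1, id2))


# ---------------------------------------------------------------------------
# Adjacency forest containers
# ---------------------------------------------------------------------------

class AdjNode:
    """A node of an adjacency tree."""

    __slots__ = ("id", "event", "species", "pair", "children", "parent", "gene_nodes")

    def __init__(
        self,
        id: str,
        event: Event,
        species: Optional[str],
        pair: Optional[Tuple[str, str]],
        gene_nodes: Optional[Tuple[TreeNode, TreeNode]] = None,
    ) -> None:
        self.id = id
        self.event = event
        self.species = species
        self.pair = pair
        self.gene_nodes = gene_nodes
        self.children: List["AdjNode"] = []
        self.parent: Optional["AdjNode"] = None

    def add_child(self, child: "AdjNode") -> "AdjNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["AdjNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<AdjNode {self.event.value}@{self.species} A={self.pair}>"


@dataclass
class AdjacencyTree:
    root: AdjNode
    gain: int = 0  # 1 when the root adjacency was a charged gain


@dataclass
class AdjacencyForest:
    trees: List[AdjacencyTree] = field(default_factory=list)
    n_gains: int = 0
    n_breaks: int = 0
    cost: float = 0

    def nodes(self) -> Iterable[AdjNode]:
        for tree in self.trees:
            yield from tree.root.postorder()

    def recompute_cost(self, model: CostModel) -> float:
        """Recount gains and breaks from the structure (consistency check)."""
        self.n_gains = sum(tree.gain for tree in self.trees)
        self.n_breaks = sum(1 for n in self.nodes() if n.event is Event.BREAK)
        self.cost = self.n_gains * model.gain_cost + self.n_breaks * model.break_cost
        return self.cost

    def extend(self, other: "AdjacencyForest") -> None:
        self.trees.extend(other.trees)
        self.n_gains += other.n_gains
        self.n_breaks += other.n_breaks
        self.cost += other.cost


# ---------------------------------------------------------------------------
# The recurrences (Cases 1-6)
# ---------------------------------------------------------------------------

def _best(options: Sequence[Tuple[float, Choice]]) -> Tuple[float, Optional[Choice]]:
    """Minimum-cost option; ties broken toward absence, then listed order."""
    best_cost, best_choice, best_rank = INF, None, None
    for cost, choice in options:
        if cost == INF:
            continue
        rank = choice.presence_rank
        if cost < best_cost or (cost == best_cost and rank < best_rank):
            best_cost, best_choice, best_rank = cost, choice, rank
    return best_cost, best_choice


def _dup_case_options(
    v_other: TreeNode,
    v_dup: TreeNode,
    flip: bool,
    cells: Dict[PairKey, Cell],
    model: CostModel,
    node_event: Event,
) -> Tuple[List[Tuple[float, Choice]], List[Tuple[float, Choice]]]:
    """Case 4 (and Case 6 D1/D2) option lists for (c1, c0).

    ``v_dup`` is the duplication node whose children ``a``, ``b`` are paired
    with ``v_other``; ``flip`` restores the (tree1, tree2) orientation of
    the child pair keys. The created node (state 1) is a one-child GDup.
    """
    a, b = v_dup.children
    key = (lambda c: (c, v_other)) if flip else (lambda c: (v_other, c))
    pa, pb = key(a), key(b)
    ca, cb = cells[pa], cells[pb]
    species = v_dup.species
    c1_options = [
        (
            ca.c1 + cb.c1 + model.gain_cost,
            Choice(event=node_event, attach=[pa], spawn=[pb]),
        ),
        (ca.c1 + cb.c0, Choice(event=node_event, attach=[pa], recurse0=[pb])),
        (ca.c0 + cb.c1, Choice(event=node_event, attach=[pb], recurse0=[pa])),
        (
            ca.c0 + cb.c0 + model.break_cost,
            Choice(event=node_event, breaks=[species], recurse0=[pa, pb]),
        ),
    ]
    c0_options = [
        (ca.c1 + cb.c1 + 2 * model.gain_cost, Choice(spawn=[pa, pb])),
        (ca.c1 + cb.c0 + model.gain_cost, Choice(spawn=[pa], recurse0=[pb])),
        (ca.c0 + cb.c1 + model.gain_cost, Choice(spawn=[pb], recurse0=[pa])),
        (ca.c0 + cb.c0, Choice(recurse0=[pa, pb])),
    ]
    return c1_options, c0_options


def _paired_case_options(
    pa: PairKey,
    pb: PairKey,
    cells: Dict[PairKey, Cell],
    model: CostModel,
    node_event: Event,
) -> Tuple[List[Tuple[float, Choice]], List[Tuple[float, Choice]]]:
    """Case 5 (and Case 6 D12) option lists for (c1, c0).

    ``pa`` and ``pb`` are the two species-matched child pairs. The created
    node (state 1) is a two-child Spec or ADup node; an absent child pair
    under a present node is a Break leaf.
    """
    ca, cb = cells[pa], cells[pb]
    sa = pa[0].species
    sb = pb[0].species
    c1_options = [
        (ca.c1 + cb.c1, Choice(event=node_event, attach=[pa, pb])),
        (
            ca.c1 + cb.c0 + model.break_cost,
            Choice(event=node_event, attach=[pa], breaks=[sb], recurse0=[pb]),
        ),
        (
            ca.c0 + cb.c1 + model.break_cost,
            Choice(event=node_event, attach=[pb], breaks=[sa], recurse0=[pa]),
        ),
        (
            ca.c0 + cb.c0 + 2 * model.break_cost,
            Choice(event=node_event, breaks=[sa, sb], recurse0=[pa, pb]),
        ),
    ]
    c0_options = [
        (ca.c1 + cb.c1 + 2 * model.gain_cost, Choice(spawn=[pa, pb])),
        (ca.c1 + cb.c0 + model.gain_cost, Choice(spawn=[pa], recurse0=[pb])),
        (ca.c0 + cb.c1 + model.gain_cost, Choice(spawn=[pb], recurse0=[pa])),
        (ca.c0 + cb.c0, Choice(recurse0=[pa, pb])),
    ]
    return c1_options, c0_options


def _adup_options(
    pa: PairKey,
    pb: PairKey,
    qa: PairKey,
    qb: PairKey,
    cells: Dict[PairKey, Cell],
    model: CostModel,
) -> List[Tuple[float, Choice]]:
    """Simultaneous-duplication (ADup) options for one child pairing.

    The ADup node descends into the paired child pairs ``pa``/``pb``; the
    two cross pairs ``qa``/``qb`` can hang from no node once this pairing
    is chosen, so the adjacencies inside each cross subtree pair form an
    independent forest costing ``min(c0, c1 + C(Gain))``.
    """
    base = _paired_case_options(pa, pb, cells, model, Event.ADUP)[0]
    options: List[Tuple[float, Choice]] = []
    for cost, choice in base:
        for cross in (qa, qb):
            cell = cells[cross]
            if cell.c0 <= cell.c1 + model.gain_cost:
                cost += cell.c0
                choice.recurse0.append(cross)
            else:
                cost += cell.c1 + model.gain_cost
                choice.spawn.append(cross)
        options.append((cost, choice))
    return options


def compute_costs(cls: AdjacencyClass, model: CostModel) -> CostTable:
    """Fill the c0/c1 table over all species-matched node pairs of a class."""
    adjacent = {frozenset((id(a), id(b))) for a, b in cls.adjacencies}
    cells: Dict[PairKey, Cell] = {}

    nodes2_by_species: Dict[str, List[TreeNode]] = {}
    for n2 in cls.tree2_root.postorder():
        nodes2_by_species.setdefault(n2.species, []).append(n2)

    for v1 in cls.tree1_root.postorder():
        for v2 in nodes2_by_species.get(v1.species, ()):
            cells[(v1, v2)] = _compute_cell(v1, v2, adjacent, cells, model)

    root_pair = (cls.tree1_root, cls.tree2_root)
    if root_pair not in cells:
        raise InputError(
            f"class {cls.class_id}: root pair is not species-matched"
        )
    return CostTable(cells=cells, root_pair=root_pair)


def _compute_cell(
    v1: TreeNode,
    v2: TreeNode,
    adjacent: set,
    cells: Dict[PairKey, Cell],
    model: CostModel,
) -> Cell:
    e1, e2 = v1.event, v2.event

    # Cases 1-3: leaf pairs.
    if e1 is Event.GLOS and e2 is Event.GLOS:
        return Cell(0, 0, Choice(), Choice(event=Event.ALOS), "case3")
    if e1 is Event.GLOS or e2 is Event.GLOS:
        return Cell(0, 0, Choice(), Choice(event=Event.GLOS), "case2")
    if e1 is Event.EXTANT and e2 is Event.EXTANT:
        if frozenset((id(v1), id(v2))) in adjacent:
            return Cell(INF, 0, None, Choice(event=Event.EXTANT), "case1")
        return Cell(0, INF, Choice(), None, "case1")

    # Case 6: both duplications.
    if e1 is Event.GDUP and e2 is Event.GDUP:
        d1_c1, d1_c0 = _dup_case_options(v2, v1, True, cells, model, Event.GDUP)
        d2_c1, d2_c0 = _dup_case_options(v1, v2, False, cells, model, Event.GDUP)
        a1, b1 = v1.children
        a2, b2 = v2.children
        d12_first = _adup_options(
            (a1, a2), (b1, b2), (a1, b2), (b1, a2), cells, model
        )
        d12_second = _adup_options(
            (a1, b2), (b1, a2), (a1, a2), (b1, b2), cells, model
        )
        c1, bp1 = _best(d1_c1 + d2_c1 + d12_first + d12_second)
        c0, bp0 = _best(d1_c0 + d2_c0)
        return Cell(c0, c1, bp0, bp1, "case6")

    # Case 4: one duplication against an extant/speciation node.
    if e2 is Event.GDUP:
        c1_opts, c0_opts = _dup_case_options(v1, v2, False, cells, model, Event.GDUP)
        c1, bp1 = _best(c1_opts)
        c0, bp0 = _best(c0_opts)
        return Cell(c0, c1, bp0, bp1, "case4")
    if e1 is Event.GDUP:
        c1_opts, c0_opts = _dup_case_options(v2, v1, True, cells, model, Event.GDUP)
        c1, bp1 = _best(c1_opts)
        c0, bp0 = _best(c0_opts)
        return Cell(c0, c1, bp0, bp1, "case4")

    # Case 5: two speciation nodes; match children by species.
    if e1 is Event.SPEC and e2 is Event.SPEC:
        a1, b1 = v1.children
        children2 = {c.species: c for c in v2.children}
        if a1.species not in children2 or b1.species not in children2:
            raise InputError(
                f"speciation pair ({v1.id}, {v2.id}): children species do not "
                "match (reconciliation broken)"
            )
        pa = (a1, children2[a1.species])
        pb = (b1, children2[b1.species])
        c1_opts, c0_opts = _paired_case_options(pa, pb, cells, model, Event.SPEC)
        c1, bp1 = _best(c1_opts)
        c0, bp0 = _best(c0_opts)
        return Cell(c0, c1, bp0, bp1, "case5")

    raise InputError(
        f"unexpected event pair ({e1}, {e2}) for species-matched nodes "
        f"({v1.id}, {v2.id})"
    )


def min_forest_cost(table: CostTable) -> float:
    """min(c0, c1) at the class root pair (root adjacency gain is free)."""
    root = table.cells[table.root_pair]
    return min(root.c0, root.c1)


# ---------------------------------------------------------------------------
# Backtracking
# ---------------------------------------------------------------------------

def backtrack(
    table: CostTable,
    cls: AdjacencyClass,
    model: CostModel,
    node_ids: Optional[Iterable[int]] = None,
) -> AdjacencyForest:
    """Materialize one optimal adjacency forest for a class.

    The root pair's state is chosen as ``argmin(c0, c1)`` with ties going
    to absence; every ``C(Gain)`` term selected along the way starts a new
    adjacency tree whose gain is charged, while a tree rooted at the class
    root pair itself is a free gain. Node identifiers are drawn from
    ``node_ids`` (fresh per call by default) so repeated runs on the same
    inputs produce identical output.
    """
    forest = AdjacencyForest()
    counter = iter(node_ids) if node_ids is not None else itertools.count(1)

    def new_node(pair: PairKey, event: Event) -> AdjNode:
        v1, v2 = pair
        return AdjNode(
            id=f"a{next(counter)}",
            event=event,
            species=v1.species,
            pair=(v1.id, v2.id),
            gene_nodes=(v1, v2),
        )

    def expand(pair: PairKey, state: int, parent: Optional[AdjNode], gain: int) -> None:
        cell = table.cells[pair]
        choice = cell.bp1 if state == 1 else cell.bp0
        if choice is None:
            raise InputError(f"backtracking into an infinite-cost cell {pair}")
        if state == 1:
            node = new_node(pair, choice.event)
            if parent is None:
                forest.trees.append(AdjacencyTree(root=node, gain=gain))
            else:
                parent.add_child(node)
            for species in choice.breaks:
                node.add_child(
                    AdjNode(
                        id=f"a{next(counter)}",
                        event=Event.BREAK,
                        species=species,
                        pair=None,
                    )
                )
            for child_pair in choice.attach:
                expand(child_pair, 1, node, 0)
        for child_pair in choice.spawn:
            expand(child_pair, 1, None, 1)
        for child_pair in choice.recurse0:
            expand(child_pair, 0, None, 0)

    root = table.cells[table.root_pair]
    root_state = 1 if root.c1 < root.c0 else 0
    expand(table.root_pair, root_state, None, 0)
    forest.recompute_cost(model)
    return forest


# ---------------------------------------------------------------------------
# Forest validation
# ---------------------------------------------------------------------------

def validate_forest(
    forest: AdjacencyForest,
    adjacencies: Sequence[AdjacencyRecord],
    leaf_of: Dict[str, TreeNode],
) -> List[str]:
    """Check every adjacency-tree clause on a forest; returns violations.

    Clauses: event domains on leaves/internals, species agreement between a
    node and its gene-node pair, per-event constraints on the underlying
    gene-node events, child-couple descent rules for Spec/ADup/GDup nodes,
    Break nodes being leaves, uniqueness of A(N) over the forest, and every
    extant adjacency labeling exactly one Extant leaf.
    """
    problems: List[str] = []
    seen_pairs: Dict[frozenset, str] = {}
    extant_seen: Dict[AdjacencyRecord, int] = {r: 0 for r in adjacencies}
    leaf_events = {Event.EXTANT, Event.GLOS, Event.ALOS, Event.BREAK}
    internal_events = {Event.SPEC, Event.GDUP, Event.ADUP}

    for node in forest.nodes():
        tag = f"node {node.id} ({node.event.value})"
        if node.is_leaf and node.event not in leaf_events:
            problems.append(f"{tag}: not a valid leaf event")
        if not node.is_leaf and node.event not in internal_events:
            problems.append(f"{tag}: not a valid internal event")
        if node.event is Event.BREAK:
            if node.pair is not None:
                problems.append(f"{tag}: Break node carries a gene pair")
            continue
        if node.gene_nodes is None:
            continue  # round-tripped forests carry ids only
        x, y = node.gene_nodes
        if not (node.species == x.species == y.species):
            problems.append(f"{tag}: species mismatch with gene nodes")
        key = frozenset((id(x), id(y)))
        if key in seen_pairs:
            problems.append(f"{tag}: duplicate A(N) with {seen_pairs[key]}")
        seen_pairs[key] = node.id
        if node.event is Event.EXTANT:
            if x.gene is None or y.gene is None:
                problems.append(f"{tag}: extant node on non-extant gene nodes")
            else:
                record = AdjacencyRecord(x.gene, y.gene)
                if record not in extant_seen:
                    problems.append(f"{tag}: {record} is not an input adjacency")
                else:
                    extant_seen[record] += 1
        elif node.event is Event.GLOS:
            if (x.event is Event.GLOS) == (y.event is Event.GLOS):
                problems.append(f"{tag}: exactly one gene must be a loss")
        elif node.event is Event.ALOS:
            if not (x.event is Event.GLOS and y.event is Event.GLOS):
                problems.append(f"{tag}: both genes must be losses")
        elif node.event in (Event.SPEC, Event.ADUP):
            wanted = Event.SPEC if node.event is Event.SPEC else Event.GDUP
            if not (x.event is wanted and y.event is wanted):
                problems.append(f"{tag}: gene events must both be {wanted.value}")
            if len(node.children) != 2:
                problems.append(f"{tag}: must have two children")
            for child in node.children:
                if child.event is Event.BREAK:
                    continue
                cx, cy = child.gene_nodes
                if not (cx in x.children and cy in y.children) and not (
                    cy in x.children and cx in y.children
                ):
                    problems.append(
                        f"{tag}: child {child.id} is not a couple of children"
                    )
        elif node.event is Event.GDUP:
            if not (x.event is Event.GDUP or y.event is Event.GDUP):
                problems.append(f"{tag}: neither gene is a duplication")
            if len(node.children) != 1:
                problems.append(f"{tag}: GDup node must have exactly one child")
            for child in node.children:
                if child.event is Event.BREAK:
                    continue
                cx, cy = child.gene_nodes
                ok = (
                    (cx is x and cy in y.children)
                    or (cy is x and cx in y.children)
                    or (cx is y and cy in x.children)
                    or (cy is y and cx in x.children)
                )
                if not ok:
                    problems.append(
                        f"{tag}: child {child.id} does not keep one gene and "
                        "descend the other"
                    )

    for record, count in extant_seen.items():
        if count != 1:
            problems.append(
                f"extant adjacency {record} labels {count} leaves (expected 1)"
            )
    return problems


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    forest: AdjacencyForest
    tables: List[CostTable]
    classes: List[AdjacencyClass]
    gene_trees: List[TreeNode]
    species_root: TreeNode
    summary: Dict[str, object]


def run(
    species_root: TreeNode,
    gene_trees: Sequence[TreeNode],
    adjacencies: Sequence[AdjacencyRecord],
    model: CostModel = CostModel(),
    trust_annotations: bool = False,
) -> RunResult:
    """Reconcile, cluster, solve each class and union the forests.

    With ``trust_annotations`` the gene trees must already satisfy the
    reconciled-tree properties (they are validated, not recomputed);
    otherwise LCA reconciliation is (re)applied.
    """
    species_index = SpeciesIndex(species_root)
    reconciled: List[TreeNode] = []
    for tree in gene_trees:
        if trust_annotations:
            report = validate_reconciled(tree, species_index, check_lca=False)
            if not report.ok:
                raise InputError(
                    "gene tree fails reconciled-tree validation:\n  "
                    + "\n  ".join(report.violations)
                )
            reconciled.append(tree)
        else:
            reconciled.append(reconcile(tree, species_index))

    leaf_of = validate_inputs(reconciled, adjacencies)
    classes = cluster_adjacencies(adjacencies, reconciled, species_index)

    forest = AdjacencyForest()
    tables: List[CostTable] = []
    per_class: List[Dict[str, object]] = []
    node_ids = itertools.count(1)
    for cls in classes:
        table = compute_costs(cls, model)
        class_forest = backtrack(table, cls, model, node_ids=node_ids)
        optimum = min_forest_cost(table)
        if class_forest.cost != optimum:
            raise AssertionError(
                f"class {cls.class_id}: backtracked cost {class_forest.cost} "
                f"!= DP optimum {optimum}"
            )
        forest.extend(class_forest)
        tables.append(table)
        per_class.append(
            {
                "class_id": cls.class_id,
                "n_adjacencies": len(cls.adjacencies),
                "n_pairs": table.n_pairs,
                "cost": optimum,
                "gains": class_forest.n_gains,
                "breaks": class_forest.n_breaks,
            }
        )

    summary: Dict[str, object] = {
        "n_gene_trees": len(reconciled),
        "n_adjacencies": len(adjacencies),
        "n_classes": len(classes),
        "n_pairs_total": sum(t.n_pairs for t in tables),
        "gain_cost": model.gain_cost,
        "break_cost": model.break_cost,
        "total_gains": forest.n_gains,
        "total_breaks": forest.n_breaks,
        "total_cost": forest.cost,
        "classes": per_class,
    }
    return RunResult(
        forest=forest,
        tables=tables,
        classes=classes,
        gene_trees=reconciled,
        species_root=species_root,
        summary=summary,
    )
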