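"""Synthetic gene-order evolution and independent verification oracles.

The simulator evolves a single linear ancestral chromosome along a random
(Yule-shaped) species tree under single-gene duplications (tandem or
dispersed), gene losses and inversions, emitting a species tree, true
event-annotated gene trees, extant adjacencies, and ground truth
(per-species gene orders and gain/break counts of the true scenario).

Two oracles validate the dynamic program independently of it:

* :func:`brute_force_min_cost` enumerates every adjacency forest a class
  admits (presence assignments x duplication orderings x attachment
  choices) and returns the cheapest cost;
* :func:`sankoff_binary` is the two-state Sankoff parsimony the DP must
  collapse to when gene trees are duplication- and loss-free.

Truth accounting follows the inference model's conventions: a tandem
duplicate's adjacency to its sibling is a free gain; when a loss rejoins
the two neighbors of the lost gene, the rejoined adjacency is counted as
a gain (the model does not grant that rejoining for free); an inversion
strictly inside a chromosome costs 2 breaks + 2 gains, one touching a
chromosome end 1 + 1, and a full-chromosome inversion nothing (adjacency
pairs are unordered).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .classes import AdjacencyClass
from .core import INF, CostModel
from .trees import AdjacencyRecord, AdjForestError, Event, TreeNode

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate",
    "write_dataset",
    "brute_force_min_cost",
    "sankoff_binary",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Rates are expected events per gene per species-tree branch; the
    ancestral genome is one linear chromosome. The same seed always
    reproduces the same dataset.
    """

    n_species: int = 6
    n_ancestral_genes: int = 20
    dup_rate: float = 0.05
    loss_rate: float = 0.05
    rearrangement_rate: float = 0.05
    tandem_fraction: float = 0.5
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_ancestral_genes < 1:
            raise AdjForestError("need at least one species and one gene")
        if min(self.dup_rate, self.loss_rate, self.rearrangement_rate) < 0:
            raise AdjForestError("rates must be >= 0")
        if not 0 <= self.tandem_fraction <= 1:
            raise AdjForestError("tandem_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """What actually happened in the simulation."""

    genomes: Dict[str, List[str]] = field(default_factory=dict)
    adjacencies: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    gains: int = 0
    breaks: int = 0
    gene_dups: int = 0
    adj_dups: int = 0
    losses: int = 0

    @property
    def total_cost_unit(self) -> int:
        return self.gains + self.breaks


@dataclass
class SimulatedDataset:
    species_root: TreeNode
    gene_trees: List[TreeNode]
    adjacencies: List[AdjacencyRecord]
    truth: GroundTruth
    config: SimulationConfig
    n_extinct_families: int = 0


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def _random_species_tree(n: int, rng: np.random.Generator) -> TreeNode:
    """Yule-shaped topology: split a uniformly chosen leaf until n leaves."""
    root = TreeNode("tmp")
    leaves = [root]
    while len(leaves) < n:
        node = leaves.pop(int(rng.integers(len(leaves))))
        left, right = TreeNode("tmp"), TreeNode("tmp")
        node.add_child(left)
        node.add_child(right)
        leaves.extend([left, right])
    leaf_counter = itertools.count(1)
    anc_counter = itertools.count(1)
    for node in root.postorder():
        if node.is_leaf:
            node.id = f"sp{next(leaf_counter)}"
            node.event = Event.EXTANT
        else:
            node.id = f"anc{next(anc_counter)}"
            node.event = Event.SPEC
        node.species = node.id
    return root


# ---------------------------------------------------------------------------
# Genome evolution
# ---------------------------------------------------------------------------

class _Extinction(AdjForestError):
    pass


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Simulate one dataset; retries (bounded) if a lineage loses all genes."""
    last_error: Optional[Exception] = None
    for attempt in range(config.max_retries):
        rng = np.random.default_rng(config.seed + 100003 * attempt)
        try:
            return _simulate_once(config, rng)
        except _Extinction as exc:
            last_error = exc
    raise AdjForestError(
        f"simulation failed after {config.max_retries} retries: {last_error}"
    )


def _simulate_once(
    config: SimulationConfig, rng: np.random.Generator
) -> SimulatedDataset:
    species_root = _random_species_tree(config.n_species, rng)
    truth = GroundTruth()
    node_counter = itertools.count(1)
    gene_counter = itertools.count(1)
    family_roots: List[TreeNode] = []
    extant_adjacencies: List[AdjacencyRecord] = []

    def fresh(fam: int, species: str) -> TreeNode:
        return TreeNode(id=f"f{fam}n{next(node_counter)}", species=species)

    root_genome: List[TreeNode] = []
    for fam in range(1, config.n_ancestral_genes + 1):
        node = fresh(fam, species_root.species)
        family_roots.append(node)
        root_genome.append(node)

    def record(species: str, genome: List[TreeNode]) -> None:
        truth.genomes[species] = [n.id for n in genome]
        truth.adjacencies[species] = {
            tuple(sorted((a.id, b.id))) for a, b in zip(genome, genome[1:])
        }

    def family_of(node: TreeNode) -> int:
        return int(node.id[1:].split("n")[0])

    def evolve_branch(genome: List[TreeNode], species: str) -> List[TreeNode]:
        # copy each lineage into the branch (children of the Spec parent)
        out: List[TreeNode] = []
        for x in genome:
            y = fresh(family_of(x), species)
            x.add_child(y)
            out.append(y)
        n = len(out)
        events = (
            ["dup"] * int(rng.poisson(config.dup_rate * n))
            + ["loss"] * int(rng.poisson(config.loss_rate * n))
            + ["inv"] * int(rng.poisson(config.rearrangement_rate * n))
        )
        rng.shuffle(events)
        for kind in events:
            if not out:
                break
            if kind == "dup":
                i = int(rng.integers(len(out)))
                y = out[i]
                y.event = Event.GDUP
                c1 = fresh(family_of(y), species)
                c2 = fresh(family_of(y), species)
                y.add_child(c1)
                y.add_child(c2)
                truth.gene_dups += 1
                if rng.random() < config.tandem_fraction or len(out) == 1:
                    out[i:i + 1] = [c1, c2]  # free sibling adjacency
                else:
                    out[i] = c1
                    j = int(rng.integers(len(out) + 1))
                    # avoid re-creating the (free) sibling adjacency
                    while j in (i, i + 1) and len(out) > 1:
                        j = int(rng.integers(len(out) + 1))
                    had_left = j > 0
                    had_right = j < len(out)
                    if had_left and had_right:
                        truth.breaks += 1
                    truth.gains += int(had_left) + int(had_right)
                    out.insert(j, c2)
            elif kind == "loss":
                i = int(rng.integers(len(out)))
                y = out.pop(i)
                y.event = Event.GLOS
                truth.losses += 1
                if 0 < i < len(out):
                    truth.gains += 1  # neighbors rejoin; not free in the model
            else:  # inversion
                if len(out) < 2:
                    continue
                i = int(rng.integers(len(out)))
                j = int(rng.integers(len(out)))
                i, j = min(i, j), max(i, j)
                if i == j or (i == 0 and j == len(out) - 1):
                    continue
                changed = int(i > 0) + int(j < len(out) - 1)
                truth.breaks += changed
                truth.gains += changed
                out[i:j + 1] = reversed(out[i:j + 1])
        return out

    def descend(snode: TreeNode, genome: List[TreeNode]) -> None:
        if not genome:
            raise _Extinction(f"all genes lost entering {snode.species}")
        record(snode.species, genome)
        if snode.is_leaf:
            for x in genome:
                x.event = Event.EXTANT
                x.gene = f"g{next(gene_counter)}"
                x.id = x.gene
            extant_adjacencies.extend(
                AdjacencyRecord(a.gene, b.gene)
                for a, b in zip(genome, genome[1:])
            )
            return
        for x in genome:
            x.event = Event.SPEC
        for schild in snode.children:
            descend(schild, evolve_branch(genome, schild.species))

    descend(species_root, root_genome)

    gene_trees: List[TreeNode] = []
    n_extinct = 0
    for root in family_roots:
        if any(n.event is Event.EXTANT for n in root.postorder()):
            gene_trees.append(root)
        else:
            n_extinct += 1

    return SimulatedDataset(
        species_root=species_root,
        gene_trees=gene_trees,
        adjacencies=extant_adjacencies,
        truth=truth,
        config=config,
        n_extinct_families=n_extinct,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset in the package's input formats, plus truth
    tables (per-species gene orders, adjacency sets, event counts)."""
    from pathlib import Path

    from .trees import write_adjacencies, write_gene_trees, write_species_tree

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_species_tree(dataset.species_root, outdir / "species.nwk")
    write_gene_trees(dataset.gene_trees, outdir / "gene_trees.nhx")
    write_adjacencies(dataset.adjacencies, outdir / "adjacencies.tsv")
    truth = dataset.truth
    rows = ["species\tgene_order"]
    for sp in sorted(truth.genomes):
        rows.append(f"{sp}\t{' '.join(truth.genomes[sp])}")
    (outdir / "truth_genomes.tsv").write_text("".join(r + "\n" for r in rows))
    rows = ["species\tgene_node_1\tgene_node_2"]
    for sp in sorted(truth.adjacencies):
        for a, b in sorted(truth.adjacencies[sp]):
            rows.append(f"{sp}\t{a}\t{b}")
    (outdir / "truth_adjacencies.tsv").write_text(
        "".join(r + "\n" for r in rows)
    )
    (outdir / "truth_events.tsv").write_text(
        "gains\tbreaks\tgene_dups\tadj_dups\tlosses\n"
        f"{truth.gains}\t{truth.breaks}\t{truth.gene_dups}\t"
        f"{truth.adj_dups}\t{truth.losses}\n"
    )


# ---------------------------------------------------------------------------
# Oracle 1: exhaustive adjacency-forest enumeration
# ---------------------------------------------------------------------------

def brute_force_min_cost(
    cls: AdjacencyClass, model: CostModel, max_pairs: int = 16
) -> float:
    """Minimum forest cost by exhaustive enumeration (small classes only).

    Enumerates every presence/absence assignment over the species-matched
    node pairs of the class (extant pairs are forced by the adjacency
    list), every duplication ordering for doubly-duplicated pairs, and
    every way of attaching present pairs to parent slots; counts one
    breakage per unfilled child slot and one gain per unattached present
    pair other than the class root. Completely independent of the DP's
    recurrences and back-pointers.
    """
    adjacent = {frozenset((id(a), id(b))) for a, b in cls.adjacencies}
    pairs: List[Tuple[TreeNode, TreeNode]] = []
    nodes2 = list(cls.tree2_root.postorder())
    for v1 in cls.tree1_root.postorder():
        for v2 in nodes2:
            if v1.species == v2.species:
                pairs.append((v1, v2))
    if len(pairs) > max_pairs:
        raise AdjForestError(
            f"{len(pairs)} species-matched pairs exceed the brute-force "
            f"bound {max_pairs}"
        )

    index = {(id(p[0]), id(p[1])): k for k, p in enumerate(pairs)}
    root_index = index[(id(cls.tree1_root), id(cls.tree2_root))]

    forced: Dict[int, bool] = {}
    free: List[int] = []
    for k, (v1, v2) in enumerate(pairs):
        if v1.event is Event.EXTANT and v2.event is Event.EXTANT:
            forced[k] = frozenset((id(v1), id(v2))) in adjacent
        else:
            free.append(k)

    def child_key(a: TreeNode, b: TreeNode) -> Optional[int]:
        return index.get((id(a), id(b)))

    def modes_for(k: int) -> List[List[Tuple[str, List[Optional[int]]]]]:
        """Slot structures available to a present internal pair.

        Each mode is a list of slots; a slot is ("one", candidates) for a
        single-child node choosing among candidate pairs, or
        ("fixed", [pair]) for a two-child node slot bound to one pair.
        """
        v1, v2 = pairs[k]
        e1, e2 = v1.event, v2.event
        if e1 is Event.GLOS or e2 is Event.GLOS:
            return [[]]  # leaf node (GLos/ALos): no slots
        if e1 is Event.EXTANT and e2 is Event.EXTANT:
            return [[]]
        modes: List[List[Tuple[str, List[Optional[int]]]]] = []
        if e1 is Event.GDUP and e2 is Event.GDUP:
            a1, b1 = v1.children
            a2, b2 = v2.children
            modes.append([("one", [child_key(a1, v2), child_key(b1, v2)])])
            modes.append([("one", [child_key(v1, a2), child_key(v1, b2)])])
            modes.append(
                [("fixed", [child_key(a1, a2)]), ("fixed", [child_key(b1, b2)])]
            )
            modes.append(
                [("fixed", [child_key(a1, b2)]), ("fixed", [child_key(b1, a2)])]
            )
        elif e2 is Event.GDUP:
            a2, b2 = v2.children
            modes.append([("one", [child_key(v1, a2), child_key(v1, b2)])])
        elif e1 is Event.GDUP:
            a1, b1 = v1.children
            modes.append([("one", [child_key(a1, v2), child_key(b1, v2)])])
        else:  # Spec, Spec
            a1, b1 = v1.children
            by_species = {c.species: c for c in v2.children}
            modes.append(
                [
                    ("fixed", [child_key(a1, by_species[a1.species])]),
                    ("fixed", [child_key(b1, by_species[b1.species])]),
                ]
            )
        return modes

    best = INF

    def assign(i: int, present: Dict[int, bool]) -> None:
        nonlocal best
        if i == len(free):
            evaluate(present)
            return
        for state in (False, True):
            present[free[i]] = state
            assign(i + 1, present)
        del present[free[i]]

    def evaluate(present_map: Dict[int, bool]) -> None:
        nonlocal best
        present = {k for k, v in {**forced, **present_map}.items() if v}
        internal = sorted(
            k
            for k in present
            if pairs[k][0].event in (Event.SPEC, Event.GDUP)
            or pairs[k][1].event in (Event.SPEC, Event.GDUP)
        )
        # leaf-like present pairs whose both events are GLos/Extant have no
        # slots; pairs with one GLos side are leaves too even if the other
        # side is internal
        def is_leaf_pair(k: int) -> bool:
            v1, v2 = pairs[k]
            return (
                v1.event is Event.GLOS
                or v2.event is Event.GLOS
                or (v1.event is Event.EXTANT and v2.event is Event.EXTANT)
            )

        slot_holders = [k for k in internal if not is_leaf_pair(k)]

        def over_modes(idx: int, slots: List[Tuple[int, str, List[int]]]) -> None:
            # accumulate the slot list over all present slot-holding pairs
            nonlocal best
            if idx == len(slot_holders):
                fill_slots(0, slots, set(), 0)
                return
            k = slot_holders[idx]
            for mode in modes_for(k):
                filtered = [
                    (k, kind, [c for c in cands if c is not None and c in present])
                    for kind, cands in mode
                ]
                over_modes(idx + 1, slots + filtered)

        def fill_slots(
            idx: int,
            slots: List[Tuple[int, str, List[int]]],
            consumed: Set[int],
            breaks: int,
        ) -> None:
            nonlocal best
            base = breaks * model.break_cost
            if base >= best:
                return
            if idx == len(slots):
                gains = sum(
                    1
                    for k in present
                    if k not in consumed and k != root_index
                )
                total = base + gains * model.gain_cost
                if total < best:
                    best = total
                return
            _, kind, candidates = slots[idx]
            options = [c for c in candidates if c not in consumed]
            for c in options:
                fill_slots(idx + 1, slots, consumed | {c}, breaks)
            # the slot may always be a Break leaf instead
            fill_slots(idx + 1, slots, consumed, breaks + 1)

        over_modes(0, [])

    assign(0, {})
    return best


# ---------------------------------------------------------------------------
# Oracle 2: binary-character Sankoff parsimony on the species tree
# ---------------------------------------------------------------------------

def sankoff_binary(
    species_root: TreeNode,
    leaf_states: Dict[str, int],
    model: CostModel,
) -> float:
    """Two-state (absent/present) Sankoff cost with a cost-free root gain.

    Transition costs: 0->1 is C(Gain), 1->0 is C(Break). Leaves absent
    from ``leaf_states`` count as absent. The root may take state 1 at no
    charge, mirroring the free gain at a class root.
    """
    def costs(node: TreeNode) -> Tuple[float, float]:
        if node.is_leaf:
            state = leaf_states.get(node.species, 0)
            return (0, INF) if state == 0 else (INF, 0)
        c0 = c1 = 0.0
        for child in node.children:
            k0, k1 = costs(child)
            c0 += min(k0, k1 + model.gain_cost)
            c1 += min(k1, k0 + model.break_cost)
        return c0, c1

    c0, c1 = costs(species_root)
    return min(c0, c1)
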