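# Methods

## Model

Three kinds of rooted binary annotated trees are handled. A **species
tree** has distinct species labels, `Spec` internal nodes and `Extant`
leaves. A **gene tree** describes one family of homologous genes and is
*reconciled*: every node carries a species S(N) and an event E(N); leaves
are `Extant` genes or `GLos` losses; internal nodes are `Spec` (children
map exactly to the two child species of S(N)) or `GDup` (both children map
to S(N) itself). An **adjacency tree** describes the descent of a
neighborhood relation between two genes: each non-`Break` node N carries a
pair A(N) = (X, Y) of gene-tree nodes with S(X) = S(Y) = S(N), and the
node's event is constrained by the events of X and Y (`ADup` needs two
duplications, `ALos` two losses, `GLos` exactly one, `Spec` two
speciations; a `GDup` adjacency node has a single child that keeps one
gene and descends the other). `Break` nodes are leaves recording a
rearrangement that severed the adjacency. An **adjacency forest** is a set
of adjacency trees in which no two nodes share the same pair A(N) and
every extant adjacency labels exactly one `Extant` leaf.

Only two events are charged: an adjacency **gain** costs C(Gain) and a
**breakage** costs C(Break) (both default 1; gene duplications and losses
are attributed to the gene trees and cost nothing here — charging them is
incompatible with the independence of adjacencies that the dynamic program
exploits, because one gene participates in up to two adjacencies). A tree
whose root adjacency (X, Y) satisfies P(X) = P(Y) (tandem context) or "X
is a (sub)tree root and Y is a root too or hangs below a speciation into a
different species" has a free gain: the gain either is a tandem
duplication by-product or cannot be dated within the compared subtrees.

## Equivalence classes

Extant adjacencies that could share an ancestor are clustered: two
adjacencies between the same (ordered) pair of gene trees are related when
species-matched ancestors dominate their respective extremities; two
adjacencies inside one tree are related when both extremities' LCA is the
same (necessarily a duplication) node. Classes are connected components of
this relation (networkx), processed independently and in sorted order for
reproducibility. A same-tree class is split at its duplication node, whose
two child subtrees become the class's tree pair.

Each class is then rooted at the **highest species-matched ancestor pair**
of its extremities, capped at the (sub)tree roots. This choice is
deliberate and load-bearing: at the maximal pair the free-root-gain
conditions above provably hold (at least one side is a tree root, and the
other is a root or sits below a speciation into another species); no
ancestral-presence scenario is lost, because any higher pair has
mismatched species and can host no adjacency node; and the DP domains of
distinct classes of one tree pair are provably disjoint (a shared
dominating pair would have merged the classes), so the forest-wide
uniqueness of A(N) survives the union over classes. Rooting at the
extremity LCAs instead (the smallest possible matrix) would make some
class-root gains free that the cost model charges, and would hide
cheaper scenarios in which the adjacency existed higher up and was broken
in pruned lineages.

## Recurrences

For every species-matched pair (v1, v2) of the class's two subtrees, in
post-order, two values are filled: c1 (cheapest forest with a node
(v1, v2)) and c0 (cheapest without). The case analysis is symmetric in the
two sides:

* both `Extant`: (c1, c0) = (0, ∞) if the pair is a listed adjacency,
  else (∞, 0);
* at least one `GLos`: c1 = c0 = 0 (the node, if created, is a `GLos` or
  `ALos` leaf);
* one `GDup` v2 with children a, b (other side `Extant`/`Spec`): the
  adjacency node has one child; writing cX(p) for the child-pair cells,
  c1 = min( c1(v1,a)+c1(v1,b)+C(Gain), c1(v1,a)+c0(v1,b),
  c0(v1,a)+c1(v1,b), c0(v1,a)+c0(v1,b)+C(Break) ) and
  c0 = min( c1+c1+2·C(Gain), c1+c0+C(Gain), c0+c1+C(Gain), c0+c0 ) over
  the same child pairs — c0 is exactly the product of the two independent
  per-child-pair contributions min(c0, c1 + C(Gain));
* both `Spec`, children matched by species into pairs pa, pb:
  c1 = min( c1(pa)+c1(pb), c1(pa)+c0(pb)+C(Break),
  c0(pa)+c1(pb)+C(Break), c0(pa)+c0(pb)+2·C(Break) ), c0 as in the
  duplication case;
* both `GDup`: c1 = min(D1, D2, D12) where D1/D2 apply the one-duplication
  c1 with the children of v1 (resp. v2) against the whole other node, and
  D12 (simultaneous duplication, `ADup`) takes, for each of the two child
  pairings {(a1,a2),(b1,b2)} and {(a1,b2),(b1,a2)}, the speciation-style
  c1 over the paired children **plus**, for each of the two cross pairs
  left unpaired, the independent contribution min(c0, c1 + C(Gain)).
  The cross-pair terms are essential: once the `ADup` node commits to one
  pairing, adjacencies living between the cross subtree pairs can attach
  to no node above themselves and form independent (gain-charged) trees.
  Omitting them drops forced extant leaves and undercounts the optimum —
  the brute-force oracle (below) catches this immediately. c0 is the
  better of the two one-side decompositions.

The class optimum is min(c0, c1) at the root pair; the root gain is free
(see above). Infinity is `math.inf`, absorbing under addition and never
chosen over a finite option; with integer costs all finite arithmetic
stays in exact integers.

## Backtracking and tie-breaking

Back-pointers store, per cell and state, the chosen decomposition: which
child pairs are attached as edges, which `Break` leaves are created (with
their species), which pairs start new gain-charged trees, and which pairs
are resolved absent. Backtracking from the root materializes one optimal
forest; a recount of gains and breaks from the finished structure must
reproduce the DP optimum and is asserted on every run.

Whenever costs tie, the decomposition using fewer present pairs wins
(absence preference), and the root state prefers c0; this mirrors the
duplication-free result that resolving ties toward absence keeps ancestral
genomes linear. Ties between the two `ADup` pairings fall back to the
first listed; these choices fix one optimum among possibly many co-optimal
forests.

## Genome statistics

A forest node with event `Extant`, `Spec`, `GDup` or `ADup` asserts a
present adjacency in its species; collecting them per species against the
gene content (gene-tree nodes mapped there, losses excluded) yields
ancestral genomes. Degrees count adjacencies per gene (including
degree-0 genes); the degree distribution is reported as proportions.
Branch duplication density is (`ADup` nodes at species s) / (gene-tree
nodes at s), with gene-less branches reported as missing rather than 0.
Mean duplicated-segment size per species is D_g / (D_g − D_a): a
duplicated segment of k genes contributes k gene duplications and k − 1
adjacency duplications, so isolated duplications give 1.0, a single
3-gene segment gives 3.0; D_a ≥ D_g is rejected as inconsistent. The
formula is an inference from the chain structure; treat reported segment
sizes as model-derived, not directly observed. Precision/recall of
ancestral adjacencies against simulated truth is computed per species and
micro-averaged; an empty prediction scores precision 0.

## Simulator

`simulate()` draws a Yule-shaped species-tree topology, lays
`n_ancestral_genes` (default 20) genes on one linear chromosome at the
root, and applies, on each branch, Poisson-distributed events with per-
gene-per-branch rates: duplications (default 0.05; a `tandem_fraction`,
default 0.5, of them place the copy next to the original — the sibling
adjacency is then a free gain — the rest insert it elsewhere, charging up
to one break and two gains), losses (default 0.05; the neighbors' rejoined
adjacency is counted as a gain in the truth tally, because the inference
model does not grant that rejoining for free), and inversions (default
0.05; with unordered adjacencies an internal inversion costs 2 breaks +
2 gains, an end-touching one 1 + 1, a whole-chromosome one nothing). The
defaults are the package's study conditions: low enough that neighborhoods
mostly persist (the regime in which ancestral gene order is recoverable at
all), high enough that every event type appears in a typical dataset.
Branches are unit-time; rates are per branch, not per unit length.
Lineages that lose every gene trigger a bounded retry with a derived seed.

Emitted gene trees carry the true events (duplication nodes at the species
into which the branch descends, losses as leaves). They satisfy every
local reconciled-tree clause by construction; the extant-descendant LCA
minimality can be violated below lineages that later lost all extant
descendants, so the validator checks that clause only where extant signal
remains, and the pipeline re-reconciles by LCA unless told to trust the
annotations. Tests that compare inferred cost against the true scenario
trust the annotations, so the truth is a valid scenario on the exact trees
the DP sees and parsimony lower-bounds it by construction.

What the simulator does not emulate: multi-gene segmental duplications
(the `ADup`-rich regime is covered by constructed fixtures instead),
whole-genome duplications, gene-tree inference error, transfers,
incomplete lineage sorting, multiple or circular chromosomes. Passing
tests therefore demonstrate correctness of the optimization and
calibration under the stated event model, not robustness to noisy input
trees.

## Independent verification

Two oracles validate the DP without sharing its logic. The **brute-force
oracle** enumerates, for a small class (≤ 16 species-matched pairs), every
presence assignment over the pairs (extant pairs forced by the adjacency
list), every duplication-ordering mode of doubly-duplicated pairs, and
every assignment of present pairs to parent child-slots; it counts a
breakage per unfilled slot and a gain per unattached present pair other
than the class root, and minimizes. The **Sankoff oracle** is two-state
(absent/present) parsimony on the species tree with transition costs
C(Gain) for 0→1 and C(Break) for 1→0 and a free presence at the root; on
duplication/loss-free data the DP must reproduce it class by class. The
suite checks DP = brute force on hundreds of seeded random classes across
several cost models, the Sankoff identity on 100 simulated datasets, zero
total cost under tandem-only duplication, forest validity and
cost-recount identity on every run, the gain-per-adjacency upper bound,
and the modal-degree-2 linearity signal on low-rearrangement simulations.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: oracle
equivalence uses 3-species, 4-family simulations (hundreds of classes of
≤ 12 pairs), the Sankoff and zero-cost checks use 6-species datasets of
8–12 families, and the linearity check aggregates six 8-species,
30-family runs. The complexity sanity check uses the number of DP cells
filled (species-matched pairs) as a deterministic workload proxy rather
than wall time, asserting sub-quadratic growth in both the number of gene
trees and the tree size. Costs may be any non-negative reals; determinism
is guaranteed given identical inputs and seed (sorted class order, shared
node-id counter, seeded generators; hypothesis-based tests are
derandomized).

## Known limitations

Ancestral genomes are reported as adjacency sets, not linearized
chromosome orders; degree > 2 conflicts are reported, not resolved. Only
one optimal forest is returned. No transfers, ILS, gene conversion or
non-LCA reconciliations. Gene orientation is supported only by the input
convention of encoding each gene as two extremities, which the algorithm
handles unchanged (at the price of losing tandem-duplication freeness);
no dedicated code path exists.
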