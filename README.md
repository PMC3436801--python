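# adjforest

Parsimonious reconstruction of the evolution of **gene neighborhoods**
(adjacencies) along reconciled gene trees.

Comparative genomics often needs to know not just which genes an ancestral
genome contained, but how they were ordered. `adjforest` takes

* a rooted binary **species tree** (Newick),
* a set of **gene trees**, one per gene family, reconciled against the
  species tree by the LCA method (or reconciled on the fly), and
* the **extant adjacencies** — unordered pairs of neighboring genes
  observed in today's genomes,

and computes an **adjacency forest**: a set of phylogenetic trees whose
nodes are ancestral or extant adjacencies, labeled with the event that
produced them (speciation `Spec`, gene duplication `GDup`, simultaneous
duplication of both genes `ADup`, gene loss `GLos`, loss of both genes
`ALos`, rearrangement breakage `Break`, or `Extant`). The forest minimizes
the total cost

```
  cost = (number of adjacency gains) · C(Gain)
       + (number of adjacency breakages) · C(Break)
```

over all histories consistent with the gene trees. Gains that arise from
tandem duplications, or that could predate the compared subtrees, are
free. The optimization is exact: extant adjacencies are partitioned into
independent equivalence classes, and for each class a dynamic program
fills two tables over species-matched gene-tree node pairs (v1, v2) —
c1(v1, v2), the cheapest forest in which the ancestral adjacency (v1, v2)
exists, and c0(v1, v2), the cheapest in which it does not — from which one
optimal forest is recovered by backtracking. With duplication-free trees
the method reduces to two-state Sankoff parsimony of presence/absence on
the species tree. The whole computation is O(n²k²) for n gene trees of
size at most k.

From the forest the package derives ancestral-genome summaries: per-gene
adjacency **degrees** (degree 2 = linear chromosome signal, degree > 2 =
conflict), per-branch **segmental-duplication densities** (ADup events per
ancestral gene), and **mean duplicated-segment sizes** (D_g / (D_g − D_a)
for D_g gene duplications chained by D_a adjacency duplications).

A seeded simulator (`adjforest simulate`) evolves a linear ancestral
chromosome along a species tree under tandem/dispersed duplications,
losses and inversions, emitting inputs plus ground truth; it backs the
test suite's oracle checks and is a first-class way to benchmark the
method.

## Worked example

Species tree `(A,B)C;` — two extant species and their ancestor `C`.
Family 1 is `(A|a1,B|b1)C5;` (a speciation at `C`); family 2 is
`((A|a2,B|b2)C6,(A|a3,B|b3)C7)C8;` (an ancestral duplication `C8` at `C`).
Genomes: in species A, `a1–a2`; in species B, `b1–b2` and `b1–b3`.

```
$ adjforest run -s species.nwk -g gene_trees.nwk -a adjacencies.tsv -o out
classes=1 gain_cost=1.0 break_cost=1.0 total_gains=1 total_breaks=0 total_cost=1.0
```

The DP table contains c1(C5, C8) = 1 and c0(C5, C8) = 2: asserting the
ancestral adjacency between the two family roots is cheaper than denying
it. `out/forest.nhx` holds the two adjacency trees:

```
((a1|a2[&&NHX:Ev=Extant:S=A:A=a1|a2],b1|b2[&&NHX:Ev=Extant:S=B:A=b1|b2])a2[&&NHX:Ev=Spec:S=C:A=C5|C6])a1[&&NHX:Ev=GDup:S=C:A=C5|C8:Gain=0];
b1|b3[&&NHX:Ev=Extant:S=B:A=b1|b3:Gain=1];
```

The first tree (cost 0) says the adjacency existed in the ancestor between
`C5` and `C8`, survived the duplication toward copy `C6`, and speciated
into `a1–a2` and `b1–b2`. The second tree is the adjacency `b1–b3`, gained
(cost 1) when the other duplicate landed next to `b1`. Total cost 1.
`out/ancestral_adjacencies.tsv` lists the reconstructed ancestral genome
content: `C5–C8` and `C5–C6` in ancestor `C`.

## Command-line interface

```
adjforest run      -s species.nwk -g trees.nwk -a adjacencies.tsv \
                   [--gain-cost 1 --break-cost 1 --trust-annotations] -o OUT
adjforest simulate --species 8 --genes 50 --dup-rate 0.05 --loss-rate 0.05 \
                   --rearr-rate 0.05 --tandem-frac 0.5 --seed 1 -o OUT
adjforest stats    --run-dir OUT -s species.nwk -o OUT/stats
adjforest validate -s species.nwk -g trees.nwk [-a adjacencies.tsv]
```

Gene-tree leaves follow the `SPECIES|GENE` labeling convention, or a
two-column gene-to-species map can be supplied with `-m`. All outputs are
plain text (Newick/NHX and TSV).

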