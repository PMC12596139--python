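# treecohort

Mutation-tree cohorts as first-class data.

Tumor evolution is reconstructed from sequencing data as a *mutation tree*
(event tree): a rooted tree whose root is the event-free germline state and
whose nodes are subclones, each annotated with the genomic events — point
mutations (snv), copy-number amplifications (amp) and deletions (del) —
acquired on the incoming edge. Inference tools produce such trees in many
incompatible formats, and comparing them *across patients* (or across
posterior samples for one patient) is where the biology lives: recurring
subclones, conserved evolutionary trajectories, and the fraction of a tumor
a targeted drug can reach.

`treecohort` gives computational oncologists a single canonical JSON format
for tree cohorts plus the analyses and static figures that make cohorts
comparable:

- **treecore** — the JSON interchange format with a full validator,
  deterministic writer, and TSV distance-matrix dialect
  (reference schema in `src/treecohort/data/cohort.schema.json`);
- **treeops** — root-to-node mutation profiles, canonical *matching labels*
  (a 12-hex-character hash identifying an event set across trees), edge-label
  summaries (`"3snv, 2amp, 4del"`), subclone fractions;
- **cohort** — matching-subclone groups, conserved trajectories within
  clusters, cluster summaries, display ordering;
- **distances** — order-constrained maximum matching between trees (greedy
  heuristic + exhaustive oracle), the induced distance
  `d(A,B) = 1 − |M| / max(n_A, n_B)`, pairwise matrices, k-nearest
  neighbors, classical (Torgerson) MDS;
- **annotations** — drug–gene interaction lookup from a frozen DGIdb-style
  TSV snapshot, first-acquisition nodes, drug-affected subclone sets;
- **converters** — parent-vector and edge-list importers (registry for
  custom dialects), Graphviz DOT export;
- **simulate** — a seeded synthetic cohort generator with ground-truth
  clusters and planted conserved trajectories;
- **render / cli** — deterministic SVG renderings of every view (single
  tree, cohort grid, distance heatmap, 2-D embedding) and the `treecohort`
  command-line tool.

## The core statistic

For two trees A and B whose nodes carry matching labels, a *matching with
ordering constraints* is a set of node pairs M such that each pair joins
equal-label nodes, no node is used twice, and for any two pairs (a,b),
(a′,b′): a is a proper ancestor of a′ in A **iff** b is a proper ancestor of
b′ in B. Maximizing |M| is NP-hard for unordered trees, so distances are
computed with a deterministic greedy heuristic (breadth-first over A,
closest-depth tie-break in B, best of both directions) and validated against
an exhaustive branch-and-bound oracle on small instances. The normalized
distance `1 − |M|/max(n_A,n_B)` is 0 for label-identical trees and 1 for
trees sharing no label.

## Worked example

```
$ treecohort --seed 11 simulate -o demo.json        # + demo.truth.json sidecar
$ treecohort distances demo.json -o demo_dist.tsv
$ treecohort knn --target c1_t1 -k 3 demo.json
c1_t3   0.333333
c1_t4   0.375000
c1_t2   0.400000
```

The three nearest neighbors of tree `c1_t1` are its cluster mates: e.g.
`c1_t3` is at distance 0.333, meaning two thirds of the larger tree's
subclones could be matched label-for-label in ancestor-consistent order.

```
$ treecohort trajectories --cluster 0 --min-support 1.0 demo.json
ad184d713277->576028ef1566->32898548121f        4
ad184d713277->90f91488d8a6->965849420d5d        4
```

Two conserved trajectories — chains of matching labels occurring in
ancestor order — are present in all 4 trees of cluster 0 (support 4); the
first is the simulator's planted chain.

```
$ treecohort summary --cluster 0 demo.json
section key     value   count
clinical        sex     F       2
clinical        sex     M       2
...
shared_label    32898548121f    {"del": {"G045": 3}}    4
```

The cluster summary tabulates clinical values over the cluster's trees and
lists every event set shared by at least two of them (here the deletion of
G045 with copy-number offset 3, carried by all 4 trees).

Views are exported with `treecohort render {tree|grid|heatmap|embedding}
cohort.json -o out.svg` (or `.pdf` when a PDF backend is installed);
renders are byte-deterministic for fixed inputs.

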