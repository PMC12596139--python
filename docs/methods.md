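# Methods

## Data model

A cohort is a set of named mutation trees. Each tree is rooted at an
event-free germline node; every other node (subclone) carries an event set
— a mapping `event_type → gene → detail`. For point mutations (`snv`) the
detail is a variant descriptor string; for copy-number amplifications and
deletions (`amp`, `del`) it is the integer copy-number offset relative to
the diploid state (≥ 1). Optional per-node annotations are a matching label
and a relative subclone size (present on all non-root nodes or none);
optional per-tree annotations are scalar clinical key–values. A cohort may
additionally carry a clustering (disjoint sample groups) and a precomputed
symmetric pairwise distance matrix indexed by exactly the cohort's sample
ids — the slot a user fills with distances from any external embedding
method.

Gene symbols are uppercased on ingest so that drug–gene joins are
case-insensitive; all other text is case-sensitive. Nodes are stored as a
flat list with parent pointers; nested `children` documents are accepted on
read and normalized. Unknown top-level JSON keys round-trip untouched. The
writer serializes with sorted keys, so equal cohorts produce byte-identical
files.

## Mutation profiles and matching labels

The profile of a subclone is the union of all event sets on its root path.
If the same (type, gene) event appears twice on one path with different
details, the deeper occurrence wins and a warning is logged — re-mutation
is rare in clone-level trees and keeping the most recent state is the least
surprising resolution. Profiles are monotone by construction: accumulated
event counts never decrease toward the leaves.

A matching label is the first 12 hex characters of a SHA-256 hash of the
event set's canonical serialization (sorted types, sorted genes, details
included). Twelve hex characters (48 bits) make collisions negligible at
cohort scale while staying readable in tables. Hashing includes details, so
`MYC+2` and `MYC+3` are different subclones; a `genes_only` switch hashes
the type→gene structure without details for workflows where magnitude
should not split matching groups. The root label is fixed to `ROOT` and is
excluded from all matching analyses.

Edge labels list the affected genes when a node has at most two events
(`TP53`, `MYC+2`, `CDKN2A−1`; deletions use U+2212), and per-type counts
otherwise (`3snv, 2amp, 4del`), in type order snv, amp, del, then other
types alphabetically.

## Conserved trajectories

A trajectory is a chain of matching labels `l1 → … → lk` (k ≥ 2). A tree
supports the chain when nodes labeled `l1,…,lk` can be chosen with each a
proper ancestor of the next — equivalently, all on one root-to-leaf path in
that order. Proper-ancestor order rather than parent-child contiguity is
the default because trees from different patients typically interleave
private events between shared ones; `contiguous=True` restricts to direct
edges. Chains with repeated labels are excluded (an identical event set
recurring on one path would make the trajectory graph cyclic).

For a cluster of K trees and a support fraction `min_support ∈ (0,1]`, the
support threshold is `max(ceil(min_support·K), 2)`; the default
`min_support = 1.0` is the strictest reading of "conserved in the cluster",
and the absolute floor of 2 prevents single-tree "conservation". Pairwise
conserved relations are computed first; chains are then grown over the
conserved-pair digraph, a chain being valid when every adjacent pair is
conserved and the whole chain meets the threshold. Reported trajectories
are the *maximal* valid chains — those not contained as a subsequence in
any other valid chain, which also suppresses shortcut chains like (x, z)
when (x, y, z) itself is conserved. Lowering `min_support` can only grow
the conserved-pair set (monotonicity), which the tests fuzz.

Matching-subclone groups require a label in ≥ 2 distinct trees by default;
repeats within one tree do not form a group, since cross-tree comparison is
the purpose of the labels.

## Tree distance

The matching model and the greedy heuristic are described in the README.
Design choices worth recording:

- **Order constraint.** Full order-isomorphism (ancestor iff ancestor) on
  matched pairs is the default; an `ancestor_only` mode requires only that
  ancestor relations of the first tree are preserved, not reflected.
- **Traversal and tie-breaks.** The greedy pass visits the first tree's
  nodes by depth then preorder index, and among compatible candidates picks
  the smallest |depth difference|, then the smallest preorder index. These
  tie-breaks make the heuristic fully deterministic.
- **Symmetry.** The heuristic is run in both directions and the larger
  cardinality kept, making the induced distance symmetric by construction.
- **Normalization.** `1 − |M|/max(n_A, n_B)` by default; a Jaccard-style
  `1 − |M|/(n_A + n_B − |M|)` is available. Both lie in [0, 1].
- **Oracle.** `exact_ordered_matching` is a branch-and-bound enumeration,
  refused above 10 non-root nodes per tree; the test suite additionally
  checks it against a structurally different brute-force enumerator and
  verifies greedy ≤ exact over hundreds of seeded pairs. On those small
  related pairs the greedy heuristic is in fact optimal throughout, but no
  general optimality is claimed.

k-nearest neighbors prefer a user-supplied distance matrix and fall back to
greedy matching distances, with alphabetical tie-breaks.

## Classical MDS

`mds_embed` implements Torgerson scaling: double-center `−D²/2`, take the
two largest eigenvalues of the centered matrix, and scale the eigenvectors
by their square roots. Non-positive eigenvalues contribute a zero axis (the
distance matrix then has no 2-D Euclidean representation along that
direction). Sign indeterminacy is fixed by making each axis's
largest-magnitude coordinate positive, so embeddings are deterministic. On
genuinely planar distance matrices the configuration is recovered to
machine precision (checked post-Procrustes).

## Drug–gene annotation

Interactions come from a frozen local TSV snapshot (columns `gene`, `drug`,
optional `interaction_type`, `source`); there is no live database access.
Gene tracking (which subclone *first acquired* a mutation) uses a node's
own events; drug impact uses accumulated profiles, so affected subclone
sets are downward-closed — every descendant of an affected clone is
affected. A gene carried under several event types in one node is
categorized with priority amplification > deletion > other for display. The
bundled ~20-row table is synthetic (plausible gene–drug names for tests
only); real analyses should supply an actual DGIdb export.

## Synthetic cohorts

The simulator emulates clone-level cohorts: per cluster a base tree is
grown by uniform random attachment (non-root node count uniform on
[nodes_min, nodes_max]), each node receiving `max(1, Poisson(λ))` events on
distinct genes with type uniform over {snv, amp, del}; each member tree is
the base plus a fixed number of perturbations drawn from {leaf insertion,
leaf deletion, event-set replacement}. Cluster 1 carries a planted chain of
event-identical nodes on a root path of every member; planted nodes are
protected from deletion and replacement, so recovery of the planted
trajectory is a construction guarantee (the recovered maximal chain may
extend the planted one when unperturbed base nodes are also conserved —
recovery is therefore checked as a contiguous sub-run).

Defaults: 3 clusters × 4 trees, 5–8 non-root nodes, gene pool of 50
synthetic symbols `G001…G050` (large enough that cross-cluster label
matches are rare by chance), λ = 1.5 events/node, 2 perturbations/tree,
planted chain length 3, subclone sizes uniform on [0.05, 1]. Clinical keys
default to `sex` (F/M) and `stage` (I–IV), drawn uniformly. All randomness
flows through one seeded generator; identical seeds give byte-identical
JSON.

What the simulator does **not** model: sequencing noise, read counts,
inference uncertainty, correlated event co-occurrence, driver/passenger
structure, or realistic gene frequencies. Passing tests therefore establish
the algorithms' correctness contracts (bounds, invariants, determinism,
recovery of planted structure), not performance on real tumor cohorts.

## Rendering

All views are hand-built SVG with fixed-precision coordinates, so output is
byte-stable for fixed input and options. Tree layouts use equal branch
lengths per depth level; node radii scale with the square root of the
subclone fraction when sizes are present, else are constant. Colors: a
fixed 12-color categorical palette cycled deterministically (label→color is
a pure function of the sorted label set); cluster background tints at 15%
opacity; gene highlighting red/blue/violet for amplification / deletion /
other; drug-affected subclones get a centered square marker. PDF export
uses the optional `cairosvg` backend and degrades to writing the SVG with a
warning when it is not installed.

## Problem sizes used in the verification scripts

The acceptance script measures matching bounds on 200 simulated pairs with
≤ 8 non-root nodes (exhaustive enumeration is exact there), trajectory
recovery and round-trip identity on 100 seeded cohorts of 12 trees, and
cluster separation on 100 two-cluster cohorts of 6 trees — sizes at which
the exhaustive oracles stay tractable while exercising every code path.

## Known limitations

- The greedy heuristic has no approximation guarantee; it is validated
  empirically against the exact oracle on small instances only.
- Trajectory mining enumerates chains over the conserved-pair digraph;
  pathological cohorts with very dense label sharing could make this
  expensive (real cohorts and the simulator are far from this regime).
- The validator reports JSON paths of the flat (normalized) document, so
  paths for nested-children input refer to the normalized positions.
- Distances read from a user matrix are trusted as-is beyond symmetry,
  non-negativity and index checks.
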