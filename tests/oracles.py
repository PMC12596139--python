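"""Independent brute-force oracles used to check the package's algorithms.

These deliberately share no code with the implementation paths they
verify: the matching oracle enumerates all injective label-respecting
pair sets per label class and filters by the order-isomorphism predicate;
the chain oracle enumerates every label chain over every tree.
"""

from __future__ import annotations

import itertools

import numpy as np

from treecohort.treecore import MutationTree


def brute_force_max_matching(A: MutationTree, B: MutationTree) -> int:
    """Maximum order-isomorphic label-respecting matching cardinality,
    by exhaustive enumeration of pair sets (label class by label class)."""
    la = {n: A.nodes[n].matching_label for n in A.non_root_ids()}
    lb = {n: B.nodes[n].matching_label for n in B.non_root_ids()}
    labels = sorted(set(la.values()) & set(lb.values()) - {None})
    per_label_options: list[list[tuple[tuple[str, str], ...]]] = []
    for lbl in labels:
        a_nodes = sorted(n for n, l in la.items() if l == lbl)
        b_nodes = sorted(n for n, l in lb.items() if l == lbl)
        options: list[tuple[tuple[str, str], ...]] = []
        for k in range(min(len(a_nodes), len(b_nodes)) + 1):
            for a_sub in itertools.combinations(a_nodes, k):
                for b_perm in itertools.permutations(b_nodes, k):
                    options.append(tuple(zip(a_sub, b_perm)))
        per_label_options.append(options)

    def order_iso(pairs: list[tuple[str, str]]) -> bool:
        for (a, b), (a2, b2) in itertools.combinations(pairs, 2):
            if A.is_proper_ancestor(a, a2) != B.is_proper_ancestor(b, b2):
                return False
            if A.is_proper_ancestor(a2, a) != B.is_proper_ancestor(b2, b):
                return False
        return True

    best = 0
    for combo in itertools.product(*per_label_options):
        pairs = [p for opt in combo for p in opt]
        if len(pairs) > best and order_iso(pairs):
            best = len(pairs)
    return best


def brute_force_chains(
    trees: list[MutationTree], threshold: int, max_len: int = 6
) -> set[tuple[str, ...]]:
    """All label chains (length >= 2) in proper-ancestor order supported by
    >= threshold trees, found by per-tree path enumeration."""

    def tree_chains(tree: MutationTree) -> set[tuple[str, ...]]:
        out: set[tuple[str, ...]] = set()
        ids = tree.non_root_ids()
        for leaf in ids:
            path = [n for n in tree.path_from_root(leaf) if n != tree.root_id]
            labels = [tree.nodes[n].matching_label for n in path]
            for k in range(2, min(max_len, len(labels)) + 1):
                for sub in itertools.combinations(labels, k):
                    if None not in sub and len(set(sub)) == len(sub):
                        out.add(tuple(sub))  # type: ignore[arg-type]
        return out

    counts: dict[tuple[str, ...], int] = {}
    for tree in trees:
        for chain in tree_chains(tree):
            counts[chain] = counts.get(chain, 0) + 1
    return {c for c, n in counts.items() if n >= threshold}


def procrustes_error(X: np.ndarray, Y: np.ndarray) -> float:
    """RMS residual after optimally translating/rotating/reflecting Y onto X."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, _, Vt = np.linalg.svd(Xc.T @ Yc)
    R = U @ Vt
    resid = Xc - Yc @ R.T
    return float(np.sqrt((resid ** 2).mean()))
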