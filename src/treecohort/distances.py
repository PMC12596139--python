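"""Pairwise tree comparison by order-constrained maximum matching.

Two mutation trees are compared by pairing up nodes that carry the same
matching label, subject to an ordering constraint: for any two matched
pairs (a, b) and (a', b'), a is a proper ancestor of a' in the first tree
if and only if b is a proper ancestor of b' in the second (an
order-isomorphism on the matched pairs).  Finding the maximum such
matching in unordered labeled trees is NP-hard, so the production path is
a deterministic greedy heuristic; an exhaustive branch-and-bound oracle is
provided for small instances and used to bound the heuristic in tests.

The matching cardinality |M| induces the normalized distance

    d(A, B) = 1 - |M| / max(n_A, n_B)

with n_X the number of non-root nodes, so d = 0 for label-identical trees
and d = 1 for trees sharing no labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import CapabilityError
from .treecore import DistanceMatrix, MutationTree, TreeCohort
from .treeops import ROOT_LABEL

__all__ = [
    "NodeMatching",
    "greedy_ordered_matching",
    "exact_ordered_matching",
    "tree_distance",
    "distance_matrix",
    "knn",
    "mds_embed",
]


@dataclass(frozen=True)
class NodeMatching:
    pairs: tuple[tuple[str, str], ...]
    cardinality: int
    order_consistent: bool = True


def _labels(tree: MutationTree) -> dict[str, str]:
    out = {}
    for nid in tree.non_root_ids():
        lbl = tree.nodes[nid].matching_label
        if lbl is None:
            raise CapabilityError(
                f"tree {tree.sample_id!r}: node {nid!r} lacks a matching label"
            )
        if lbl != ROOT_LABEL:
            out[nid] = lbl
    return out


def _pair_compatible(
    A: MutationTree, B: MutationTree,
    a: str, b: str, a2: str, b2: str,
    ancestor_only: bool,
) -> bool:
    aa = A.is_proper_ancestor(a, a2)
    ab = A.is_proper_ancestor(a2, a)
    ba = B.is_proper_ancestor(b, b2)
    bb = B.is_proper_ancestor(b2, b)
    if ancestor_only:
        # weaker mode: ancestor relations in A must be preserved in B,
        # but incomparable pairs in A are unconstrained
        return (not aa or ba) and (not ab or bb)
    return aa == ba and ab == bb


def _is_order_isomorphic(
    A: MutationTree, B: MutationTree,
    pairs: list[tuple[str, str]],
    ancestor_only: bool = False,
) -> bool:
    for i in range(len(pairs)):
        a, b = pairs[i]
        for j in range(i + 1, len(pairs)):
            a2, b2 = pairs[j]
            if not _pair_compatible(A, B, a, b, a2, b2, ancestor_only):
                return False
    return True


def greedy_ordered_matching(
    A: MutationTree, B: MutationTree, *, ancestor_only: bool = False
) -> NodeMatching:
    """Deterministic greedy heuristic for ordered maximum matching.

    Visits A's non-root nodes in breadth-first order (depth ascending, ties
    by preorder index) and pairs each with the unmatched equal-label node
    of B that keeps the matching order-isomorphic, preferring the smallest
    depth difference and then the smallest preorder index in B.
    """
    la, lb = _labels(A), _labels(B)
    by_label_b: dict[str, list[str]] = {}
    for nid, lbl in lb.items():
        by_label_b.setdefault(lbl, []).append(nid)

    order_a = sorted(la, key=lambda nid: (A.depth(nid), A.preorder_index(nid)))
    matched: list[tuple[str, str]] = []
    used_b: set[str] = set()
    for a in order_a:
        candidates = [
            b for b in by_label_b.get(la[a], [])
            if b not in used_b
            and all(
                _pair_compatible(A, B, a, b, a2, b2, ancestor_only)
                for a2, b2 in matched
            )
        ]
        if not candidates:
            continue
        b = min(
            candidates,
            key=lambda x: (abs(A.depth(a) - B.depth(x)), B.preorder_index(x)),
        )
        matched.append((a, b))
        used_b.add(b)
    return NodeMatching(tuple(sorted(matched)), len(matched))


def exact_ordered_matching(
    A: MutationTree, B: MutationTree, max_nodes: int = 10,
    *, ancestor_only: bool = False,
) -> NodeMatching:
    """Maximum order-isomorphic label-respecting matching, by exhaustive search.

    Branch-and-bound over A's nodes in preorder: each node is either left
    unmatched or matched to a compatible B node.  Intended as a test
    oracle; refuses trees above ``max_nodes`` non-root nodes.  Ties are
    broken toward the lexicographically smallest pair set.
    """
    if A.n_non_root() > max_nodes or B.n_non_root() > max_nodes:
        raise CapabilityError(
            f"exact matching limited to {max_nodes} non-root nodes per tree"
        )
    la, lb = _labels(A), _labels(B)
    by_label_b: dict[str, list[str]] = {}
    for nid, lbl in sorted(lb.items()):
        by_label_b.setdefault(lbl, []).append(nid)
    order_a = sorted(la)

    best: list[tuple[tuple[str, str], ...]] = [()]

    def recurse(i: int, current: list[tuple[str, str]], used_b: set[str]) -> None:
        if len(current) + (len(order_a) - i) < len(best[0]):
            return  # cannot beat the incumbent
        if i == len(order_a):
            cand = tuple(sorted(current))
            if len(cand) > len(best[0]) or (
                len(cand) == len(best[0]) and cand < best[0]
            ):
                best[0] = cand
            return
        a = order_a[i]
        for b in by_label_b.get(la[a], []):
            if b in used_b:
                continue
            if all(
                _pair_compatible(A, B, a, b, a2, b2, ancestor_only)
                for a2, b2 in current
            ):
                current.append((a, b))
                used_b.add(b)
                recurse(i + 1, current, used_b)
                current.pop()
                used_b.discard(b)
        recurse(i + 1, current, used_b)

    recurse(0, [], set())
    return NodeMatching(best[0], len(best[0]))


def tree_distance(
    A: MutationTree,
    B: MutationTree,
    method: Literal["greedy", "exact"] = "greedy",
    *,
    normalization: Literal["max", "jaccard"] = "max",
) -> float:
    """Normalized matching distance in [0, 1]; 0 iff a perfect matching exists.

    The greedy method runs both directions (A against B and B against A)
    and keeps the larger cardinality, which makes the score symmetric.
    """
    na, nb = A.n_non_root(), B.n_non_root()
    if na == 0 and nb == 0:
        return 0.0
    if method == "greedy":
        card = max(
            greedy_ordered_matching(A, B).cardinality,
            greedy_ordered_matching(B, A).cardinality,
        )
    elif method == "exact":
        card = exact_ordered_matching(A, B).cardinality
    else:
        raise ValueError(f"unknown method {method!r}")
    if normalization == "max":
        denom = max(na, nb)
    elif normalization == "jaccard":
        denom = na + nb - card
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return 1.0 - card / denom if denom else 0.0


def distance_matrix(
    cohort: TreeCohort, method: Literal["greedy", "exact"] = "greedy"
) -> DistanceMatrix:
    """All pairwise tree distances; samples ordered alphabetically."""
    ids = cohort.sample_ids()
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = tree_distance(cohort.trees[ids[i]], cohort.trees[ids[j]], method)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values)


def knn(
    cohort: TreeCohort, target: str, k: int = 5,
    method: Literal["greedy", "exact"] = "greedy",
) -> list[tuple[str, float]]:
    """The k nearest trees to ``target``, closest first.

    Uses the cohort's user-supplied distance matrix when present, else
    computes greedy matching distances on the fly.  Ties are broken
    alphabetically; fewer than k neighbors are returned for small cohorts.
    """
    if target not in cohort.trees:
        raise KeyError(f"unknown sample {target!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    others = [sid for sid in cohort.sample_ids() if sid != target]
    if cohort.distances is not None:
        dists = [(sid, cohort.distances.get(target, sid)) for sid in others]
    else:
        dists = [
            (sid, tree_distance(cohort.trees[target], cohort.trees[sid], method))
            for sid in others
        ]
    dists.sort(key=lambda t: (t[1], t[0]))
    return dists[:k]


def mds_embed(dm: DistanceMatrix) -> dict[str, tuple[float, float]]:
    """Classical (Torgerson) multidimensional scaling into the plane.

    Double-centers -D²/2, takes the two largest non-negative eigenvalues
    and the correspondingly scaled eigenvectors.  The embedding is
    deterministic: each axis's sign is fixed so its largest-magnitude
    coordinate is positive.
    """
    n = len(dm.sample_ids)
    if n < 2:
        raise CapabilityError("MDS embedding requires at least 2 samples")
    D = np.asarray(dm.values, dtype=float)
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D ** 2) @ J
    Bmat = (Bmat + Bmat.T) / 2.0
    eigval, eigvec = np.linalg.eigh(Bmat)
    order = np.argsort(eigval)[::-1]
    coords = np.zeros((n, 2))
    for axis, idx in enumerate(order[:2]):
        lam = eigval[idx]
        if lam <= 0:
            continue
        col = eigvec[:, idx] * np.sqrt(lam)
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            col = -col
        coords[:, axis] = col
    return {
        sid: (float(coords[i, 0]), float(coords[i, 1]))
        for i, sid in enumerate(dm.sample_ids)
    }
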