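"""Cohort-level analytics.

Matching subclones (nodes with the same matching label in different trees),
conserved evolutionary trajectories (ordered label chains recurring in
ancestor order across the trees of a cluster), cluster summaries, and tree
ordering for display.

A *conserved trajectory* is formalized as a chain of matching labels
``l1 → l2 → ... → lk`` such that, in each supporting tree, some node
labeled ``l_i`` is a proper ancestor of some node labeled ``l_{i+1}``
with all chosen nodes on one root-to-leaf path.  The chain need not use
contiguous parent-child edges (trees from different patients typically
differ in intermediate nodes); a strict edge-contiguous mode is available
via ``contiguous=True``.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Any, Iterable, Literal

from .errors import CapabilityError
from .treecore import EventSet, MutationTree, TreeCohort
from .treeops import ROOT_LABEL

__all__ = [
    "MatchingGroup",
    "ConservedTrajectory",
    "matching_groups",
    "conserved_pairs",
    "conserved_trajectories",
    "chain_support",
    "cluster_summary",
    "order_trees",
]


@dataclass(frozen=True)
class MatchingGroup:
    label: str
    members: tuple[tuple[str, str], ...]  # (sample_id, node_id)
    event_set: EventSet


@dataclass(frozen=True)
class ConservedTrajectory:
    labels: tuple[str, ...]
    support: int
    cluster_id: int


def _label_nodes(tree: MutationTree) -> dict[str, list[str]]:
    """label -> node_ids carrying it (non-root, labeled nodes only)."""
    out: dict[str, list[str]] = {}
    for nid in tree.non_root_ids():
        lbl = tree.nodes[nid].matching_label
        if lbl is None or lbl == ROOT_LABEL:
            continue
        out.setdefault(lbl, []).append(nid)
    return out


def _require_labels(trees: Iterable[MutationTree]) -> None:
    for t in trees:
        for nid in t.non_root_ids():
            if t.nodes[nid].matching_label is None:
                raise CapabilityError(
                    f"tree {t.sample_id!r}: node {nid!r} has no matching label; "
                    "run assign_matching_labels first"
                )


def matching_groups(
    cohort: TreeCohort,
    scope: Literal["whole-cohort", "per-cluster"] = "whole-cohort",
    *,
    min_samples: int = 2,
) -> list[MatchingGroup]:
    """Groups of nodes sharing a matching label across >= ``min_samples``
    distinct trees of the scope.

    With ``scope="per-cluster"`` groups are computed within each cluster
    separately (clusters required).  Ordering is deterministic: descending
    member count, then label.
    """
    _require_labels(cohort)
    if scope == "per-cluster":
        if cohort.clusters is None:
            raise CapabilityError("per-cluster scope requires clusters")
        scopes = [list(grp) for grp in cohort.clusters]
    elif scope == "whole-cohort":
        scopes = [cohort.sample_ids()]
    else:
        raise ValueError(f"unknown scope {scope!r}")

    groups: list[MatchingGroup] = []
    for sample_ids in scopes:
        by_label: dict[str, list[tuple[str, str]]] = {}
        events: dict[str, EventSet] = {}
        for sid in sorted(sample_ids):
            tree = cohort.trees[sid]
            for lbl, nids in _label_nodes(tree).items():
                for nid in nids:
                    by_label.setdefault(lbl, []).append((sid, nid))
                    events[lbl] = tree.nodes[nid].events
        for lbl, members in by_label.items():
            if len({sid for sid, _ in members}) >= min_samples:
                groups.append(MatchingGroup(lbl, tuple(members), events[lbl]))
    groups.sort(key=lambda g: (-len(g.members), g.label))
    return groups


def _cluster_trees(cohort: TreeCohort, cluster_id: int) -> list[MutationTree]:
    if cohort.clusters is None:
        raise CapabilityError("operation requires a cluster assignment")
    if not (0 <= cluster_id < len(cohort.clusters)):
        raise KeyError(f"unknown cluster_id {cluster_id}")
    return [cohort.trees[sid] for sid in sorted(cohort.clusters[cluster_id])]


def _support_threshold(min_support: float, n_trees: int) -> int:
    if not (0 < min_support <= 1):
        raise ValueError("min_support must be in (0, 1]")
    return max(math.ceil(min_support * n_trees), 2)


def chain_support(
    trees: list[MutationTree], labels: tuple[str, ...], *, contiguous: bool = False
) -> int:
    """Number of trees containing the whole label chain in proper-ancestor order."""
    count = 0
    for tree in trees:
        if _tree_has_chain(tree, labels, contiguous=contiguous):
            count += 1
    return count


def _tree_has_chain(
    tree: MutationTree, labels: tuple[str, ...], *, contiguous: bool
) -> bool:
    by_label = _label_nodes(tree)
    if any(lbl not in by_label for lbl in labels):
        return False

    def extend(prev_nid: str, i: int) -> bool:
        if i == len(labels):
            return True
        for nid in by_label[labels[i]]:
            if contiguous:
                ok = tree.nodes[nid].parent_id == prev_nid
            else:
                ok = tree.is_proper_ancestor(prev_nid, nid)
            if ok and extend(nid, i + 1):
                return True
        return False

    return any(extend(nid, 1) for nid in by_label[labels[0]])


def conserved_pairs(
    cohort: TreeCohort,
    cluster_id: int,
    min_support: float = 1.0,
    *,
    contiguous: bool = False,
) -> list[tuple[str, str, int]]:
    """Ordered label pairs (ancestor, descendant) recurring within a cluster.

    A pair (x, y) is reported iff at least ``max(ceil(min_support * K), 2)``
    of the cluster's K trees contain some node labeled x as a proper
    ancestor of some node labeled y.  Self-pairs (x, x) are excluded.
    Output sorted by descending support, then lexicographically.
    """
    trees = _cluster_trees(cohort, cluster_id)
    _require_labels(trees)
    threshold = _support_threshold(min_support, len(trees))

    counts: dict[tuple[str, str], int] = {}
    for tree in trees:
        by_label = _label_nodes(tree)
        seen: set[tuple[str, str]] = set()
        for anc_lbl, anc_nodes in by_label.items():
            for desc_lbl, desc_nodes in by_label.items():
                if anc_lbl == desc_lbl or (anc_lbl, desc_lbl) in seen:
                    continue
                for a in anc_nodes:
                    hit = False
                    for d in desc_nodes:
                        if contiguous:
                            ok = tree.nodes[d].parent_id == a
                        else:
                            ok = tree.is_proper_ancestor(a, d)
                        if ok:
                            seen.add((anc_lbl, desc_lbl))
                            hit = True
                            break
                    if hit:
                        break
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1

    out = [(x, y, c) for (x, y), c in counts.items() if c >= threshold]
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def conserved_trajectories(
    cohort: TreeCohort,
    cluster_id: int,
    min_support: float = 1.0,
    *,
    contiguous: bool = False,
) -> list[ConservedTrajectory]:
    """Maximal conserved label chains within a cluster.

    Chains are built over the digraph of conserved pairs; a chain is valid
    when every adjacent pair is conserved and the whole chain occurs in
    ancestor order in at least the threshold number of trees.  Only
    maximal chains are returned — those not contained (as a subsequence)
    in any other valid chain — ordered by length descending then
    lexicographically.
    """
    trees = _cluster_trees(cohort, cluster_id)
    threshold = _support_threshold(min_support, len(trees))
    pairs = conserved_pairs(cohort, cluster_id, min_support, contiguous=contiguous)
    succ: dict[str, list[str]] = {}
    pred: dict[str, list[str]] = {}
    pair_set = set()
    for x, y, _ in pairs:
        succ.setdefault(x, []).append(y)
        pred.setdefault(y, []).append(x)
        pair_set.add((x, y))

    def supported(labels: tuple[str, ...]) -> bool:
        return chain_support(trees, labels, contiguous=contiguous) >= threshold

    # grow all valid chains from the conserved pairs; cohort label graphs
    # are small so exhaustive growth is fine
    valid: dict[tuple[str, ...], int] = {}
    queue: list[tuple[str, ...]] = [
        (x, y) for (x, y) in sorted(pair_set) if supported((x, y))
    ]
    while queue:
        chain = queue.pop()
        if chain in valid:
            continue
        valid[chain] = chain_support(trees, chain, contiguous=contiguous)
        for nxt in succ.get(chain[-1], []):
            if nxt in chain:
                continue
            ext = chain + (nxt,)
            if ext not in valid and supported(ext):
                queue.append(ext)
        for prv in pred.get(chain[0], []):
            if prv in chain:
                continue
            ext = (prv,) + chain
            if ext not in valid and supported(ext):
                queue.append(ext)

    def is_subsequence(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
        it = iter(long)
        return all(lbl in it for lbl in short)

    # a chain is maximal iff no other valid chain contains it as a
    # subsequence (this also drops shortcut chains like (x, z) when
    # (x, y, z) is itself conserved)
    maximal = [
        c for c in valid
        if not any(o != c and is_subsequence(c, o) for o in valid)
    ]
    maximal.sort(key=lambda c: (-len(c), c))
    return [
        ConservedTrajectory(labels=c, support=valid[c], cluster_id=cluster_id)
        for c in maximal
    ]


def cluster_summary(cohort: TreeCohort, cluster_id: int) -> dict[str, Any]:
    """Clinical-value counts and shared matching labels for one cluster.

    Returns ``{"cluster_id", "n_trees", "clinical": {key: {value: count}},
    "shared_labels": [{"label", "events", "n_trees"}, ...]}``.  Trees
    missing a clinical key are counted under ``"NA"``.
    """
    trees = _cluster_trees(cohort, cluster_id)
    keys = sorted({k for t in trees for k in t.clinical})
    clinical: dict[str, dict[str, int]] = {}
    for key in keys:
        counts: dict[str, int] = {}
        for t in trees:
            val = str(t.clinical.get(key, "NA"))
            counts[val] = counts.get(val, 0) + 1
        clinical[key] = dict(sorted(counts.items()))

    label_trees: dict[str, set[str]] = {}
    label_events: dict[str, EventSet] = {}
    for t in trees:
        for lbl, nids in _label_nodes(t).items():
            label_trees.setdefault(lbl, set()).add(t.sample_id)
            label_events[lbl] = t.nodes[nids[0]].events
    shared = [
        {"label": lbl, "events": label_events[lbl].to_json(),
         "n_trees": len(sids)}
        for lbl, sids in label_trees.items()
        if len(sids) >= 2
    ]
    shared.sort(key=lambda rec: (-rec["n_trees"], rec["label"]))
    return {
        "cluster_id": cluster_id,
        "n_trees": len(trees),
        "clinical": clinical,
        "shared_labels": shared,
    }


def order_trees(
    cohort: TreeCohort,
    mode: Literal["clustered", "alphabetical", "random"] = "alphabetical",
    seed: int = 0,
) -> list[str]:
    """Display order of sample ids.

    ``clustered``: cluster groups in given order, alphabetical within each,
    then unclustered samples alphabetically.  ``random`` is deterministic
    for a fixed seed.
    """
    ids = cohort.sample_ids()
    if mode == "alphabetical":
        return ids
    if mode == "random":
        rng = random.Random(seed)
        out = list(ids)
        rng.shuffle(out)
        return out
    if mode == "clustered":
        if cohort.clusters is None:
            raise CapabilityError("clustered ordering requires clusters")
        out: list[str] = []
        for grp in cohort.clusters:
            out.extend(sorted(grp))
        rest = sorted(set(ids) - set(out))
        return out + rest
    raise ValueError(f"unknown mode {mode!r}")
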