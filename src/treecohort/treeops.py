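"""Per-tree computations: mutation profiles, edge labels, matching labels,
subclone fractions.

The *mutation profile* of a subclone is the union of all events collected
along the path from the root to its node — the genetic state of the cell
population the node represents.  *Matching labels* canonically identify an
event set, so that the same subclone can be recognized across different
trees of a cohort.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

from .errors import CapabilityError, DegenerateInputError
from .treecore import (
    EventSet,
    MutationTree,
    TreeCohort,
    TreeNode,
    _type_sort_key,
)

__all__ = [
    "MutationProfile",
    "node_profile",
    "edge_label",
    "canonical_label",
    "assign_matching_labels",
    "subclone_fractions",
    "ROOT_LABEL",
]

logger = logging.getLogger(__name__)

ROOT_LABEL = "ROOT"

#: U+2212 minus sign, used in deletion edge labels ("CDKN2A−1").
_MINUS = "−"


@dataclass(frozen=True)
class MutationProfile:
    node_id: str
    accumulated: EventSet


def node_profile(tree: MutationTree, node_id: str) -> MutationProfile:
    """Accumulate events along the root→node path.

    If the same (type, gene) occurs twice on the path with different
    details, the deeper node's detail wins and a warning is logged.
    """
    if node_id not in tree.nodes:
        raise KeyError(f"unknown node_id {node_id!r} in tree {tree.sample_id!r}")
    acc = EventSet()
    for nid in tree.path_from_root(node_id):
        acc, collisions = acc.union(tree.nodes[nid].events)
        for key in collisions:
            logger.warning(
                "tree %s: event %s re-acquired at node %s; deeper detail kept",
                tree.sample_id, key, nid,
            )
    return MutationProfile(node_id=node_id, accumulated=acc)


def edge_label(node: TreeNode) -> str:
    """Summarize a node's events for display on its incoming edge.

    With at most two events the genes themselves are shown —
    ``"TP53"`` for a point mutation, ``"MYC+2"`` for an amplification,
    ``"CDKN2A−1"`` for a deletion — joined by commas in type order
    snv, amp, del, then other types alphabetically.  With more than two
    events the per-type counts are shown instead, e.g. ``"3snv, 2amp, 4del"``.
    """
    if node.is_root:
        raise ValueError("edge_label is undefined for the root (no incoming edge)")
    ev = node.events
    types = sorted(ev.entries, key=_type_sort_key)
    if ev.total_count() <= 2:
        items: list[str] = []
        for etype in types:
            for gene in sorted(ev.entries[etype]):
                detail = ev.entries[etype][gene]
                if etype == "amp":
                    items.append(f"{gene}+{detail}")
                elif etype == "del":
                    items.append(f"{gene}{_MINUS}{detail}")
                else:
                    items.append(gene)
        return ", ".join(items)
    return ", ".join(f"{len(ev.entries[t])}{t}" for t in types if ev.entries[t])


def canonical_label(events: EventSet, *, genes_only: bool = False) -> str:
    """Short stable identifier of an event set.

    First 12 hex characters of SHA-256 over the canonical serialization
    (sorted types, sorted genes, details included).  ``genes_only=True``
    hashes the type→gene structure without details, for workflows where
    e.g. amplification magnitude should not split matching groups.
    """
    if genes_only:
        import json

        payload = json.dumps(
            {t: sorted(g) for t, g in events.entries.items()},
            sort_keys=True, separators=(",", ":"),
        )
    else:
        payload = events.canonical_json()
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]


def assign_matching_labels(
    cohort: TreeCohort, *, overwrite: bool = False, genes_only: bool = False
) -> TreeCohort:
    """Give every node a matching label derived from its event set.

    Identical event sets anywhere in the cohort receive identical labels;
    the root label is fixed to ``"ROOT"``.  User-provided labels are kept
    unless ``overwrite`` is set.  Returns a new cohort; the input is not
    modified.
    """
    new_trees = {}
    for sid, tree in cohort.trees.items():
        nodes = []
        for nid in sorted(tree.nodes):
            n = tree.nodes[nid]
            if n.is_root:
                label = ROOT_LABEL
            elif n.matching_label is not None and not overwrite:
                label = n.matching_label
            else:
                label = canonical_label(n.events, genes_only=genes_only)
            nodes.append(TreeNode(n.node_id, n.parent_id,
                                  EventSet(n.events.entries), label, n.size))
        new_trees[sid] = MutationTree(sid, nodes, tree.clinical)
    return TreeCohort(new_trees, cohort.clusters, cohort.distances, cohort.extra)


def subclone_fractions(tree: MutationTree) -> dict[str, float]:
    """Relative subclone cell-population fractions (non-root nodes).

    Fractions are node sizes normalized to sum to one.
    """
    non_root = tree.non_root_ids()
    if not non_root:
        return {}
    sizes = {}
    for nid in non_root:
        s = tree.nodes[nid].size
        if s is None:
            raise CapabilityError(
                f"tree {tree.sample_id!r}: node {nid!r} has no size; "
                "subclone fractions require sizes on all non-root nodes"
            )
        sizes[nid] = float(s)
    total = sum(sizes.values())
    if total <= 0:
        raise DegenerateInputError(
            f"tree {tree.sample_id!r}: all subclone sizes are zero"
        )
    return {nid: s / total for nid, s in sizes.items()}
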