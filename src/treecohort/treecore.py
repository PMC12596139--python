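"""Canonical data model for mutation-tree cohorts and its JSON interchange format.

A *mutation tree* (event tree) is a rooted tree whose root represents the
event-free germline state and whose non-root nodes are subclones, each
annotated with the set of genomic events (point mutations, copy-number
amplifications/deletions, ...) acquired on the incoming edge.  A *cohort*
is a named collection of such trees, optionally grouped into clusters and
optionally accompanied by a precomputed pairwise tree distance matrix and
per-tree clinical annotations.

The on-disk dialect is a single JSON document::

    {
      "trees": {
        "<sample_id>": {
          "nodes": [
            {"node_id": "r", "events": {}},
            {"node_id": "n1", "parent_id": "r",
             "events": {"snv": {"TP53": "p.R175H"}, "amp": {"MYC": 2}},
             "matching_label": "...",        # optional
             "size": 0.4}                    # optional
          ],
          "clinical": {"sex": "F"}           # optional
        }
      },
      "clusters": [["s1", "s2"], ["s3"]],    # optional
      "distances": {"sample_ids": [...], "matrix": [[...]]}   # optional
    }

Nodes may alternatively be given in nested form (each node carrying a
``"children"`` list instead of ``"parent_id"``); they are normalized to the
flat list on read.  Unknown top-level keys round-trip untouched.  Gene
symbols are uppercased on ingest; everything else is case-sensitive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import numpy as np

from .errors import CohortParseError, CohortValidationError

__all__ = [
    "EventSet",
    "TreeNode",
    "MutationTree",
    "TreeCohort",
    "DistanceMatrix",
    "Violation",
    "parse_cohort",
    "validate_cohort",
    "write_cohort",
    "cohort_to_json",
    "read_distance_tsv",
    "write_distance_tsv",
]

#: Event types with a fixed display rank; any other type sorts after these,
#: alphabetically.
CANONICAL_TYPE_ORDER = ("snv", "amp", "del")


def _type_sort_key(event_type: str) -> tuple[int, str]:
    try:
        return (CANONICAL_TYPE_ORDER.index(event_type), "")
    except ValueError:
        return (len(CANONICAL_TYPE_ORDER), event_type)


class EventSet:
    """Mapping event_type -> gene symbol -> detail.

    For ``"snv"`` the detail is a variant descriptor string (may be empty);
    for ``"amp"``/``"del"`` it is the positive integer copy-number change
    relative to the diploid state.  Gene symbols are uppercased on
    construction.
    """

    __slots__ = ("entries",)

    def __init__(self, entries: Mapping[str, Mapping[str, Any]] | None = None):
        norm: dict[str, dict[str, Any]] = {}
        for etype, genes in (entries or {}).items():
            norm[etype] = {str(g).upper(): d for g, d in genes.items()}
        self.entries = norm

    def total_count(self) -> int:
        return sum(len(genes) for genes in self.entries.values())

    def is_empty(self) -> bool:
        return self.total_count() == 0

    def genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.entries.values():
            out.update(genes)
        return out

    def types_for_gene(self, gene: str) -> list[str]:
        gene = gene.upper()
        return sorted(
            (t for t, genes in self.entries.items() if gene in genes),
            key=_type_sort_key,
        )

    def union(self, other: "EventSet") -> tuple["EventSet", list[str]]:
        """Merge two event sets; on a (type, gene) collision ``other`` wins.

        Returns the merged set and the list of ``"type:GENE"`` collision
        keys, so callers can log re-mutation along a path.
        """
        merged = {t: dict(g) for t, g in self.entries.items()}
        collisions: list[str] = []
        for etype, genes in other.entries.items():
            tgt = merged.setdefault(etype, {})
            for gene, detail in genes.items():
                if gene in tgt and tgt[gene] != detail:
                    collisions.append(f"{etype}:{gene}")
                tgt[gene] = detail
        return EventSet(merged), collisions

    def canonical_json(self) -> str:
        """Deterministic serialization: sorted types, sorted genes, details kept."""
        return json.dumps(self.entries, sort_keys=True, separators=(",", ":"))

    def to_json(self) -> dict[str, dict[str, Any]]:
        return {t: dict(g) for t, g in sorted(self.entries.items())}

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EventSet) and self.entries == other.entries

    def __hash__(self) -> int:
        return hash(self.canonical_json())

    def __repr__(self) -> str:
        return f"EventSet({self.entries!r})"


@dataclass
class TreeNode:
    node_id: str
    parent_id: str | None = None
    events: EventSet = field(default_factory=EventSet)
    matching_label: str | None = None
    size: float | None = None

    @property
    def is_root(self) -> bool:
        return self.parent_id is None

    def to_json(self) -> dict[str, Any]:
        d: dict[str, Any] = {"node_id": self.node_id, "events": self.events.to_json()}
        if self.parent_id is not None:
            d["parent_id"] = self.parent_id
        if self.matching_label is not None:
            d["matching_label"] = self.matching_label
        if self.size is not None:
            d["size"] = self.size
        return d


class MutationTree:
    """A rooted tree of subclones for one tumor sample.

    Structural helpers (children, depth, preorder index, ancestor tests) are
    computed once at construction; trees are treated as immutable — mutate
    by building a new instance.
    """

    def __init__(
        self,
        sample_id: str,
        nodes: Sequence[TreeNode],
        clinical: Mapping[str, Any] | None = None,
    ):
        self.sample_id = sample_id
        self.nodes: dict[str, TreeNode] = {}
        for n in nodes:
            if n.node_id in self.nodes:
                raise ValueError(f"duplicate node_id {n.node_id!r} in tree {sample_id!r}")
            self.nodes[n.node_id] = n
        self.clinical: dict[str, Any] = dict(clinical or {})
        roots = [n.node_id for n in nodes if n.is_root]
        if len(roots) != 1:
            raise ValueError(f"tree {sample_id!r} has {len(roots)} roots, expected 1")
        self.root_id: str = roots[0]
        self._children: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for n in nodes:
            if n.parent_id is not None:
                if n.parent_id not in self.nodes:
                    raise ValueError(
                        f"node {n.node_id!r}: parent reference {n.parent_id!r} unresolved"
                    )
                self._children[n.parent_id].append(n.node_id)
        # child order follows input node order, which write_cohort sorts
        self._depth: dict[str, int] = {}
        self._preorder: list[str] = []
        stack = [(self.root_id, 0)]
        while stack:
            nid, d = stack.pop()
            self._depth[nid] = d
            self._preorder.append(nid)
            for c in reversed(self._children[nid]):
                stack.append((c, d + 1))
        if len(self._preorder) != len(self.nodes):
            raise ValueError(f"tree {sample_id!r} is not connected/acyclic")
        self._preorder_index = {nid: i for i, nid in enumerate(self._preorder)}
        self._ancestors: dict[str, frozenset[str]] = {}
        for nid in self._preorder:
            p = self.nodes[nid].parent_id
            self._ancestors[nid] = (
                frozenset() if p is None else self._ancestors[p] | {p}
            )

    # -- structure queries -------------------------------------------------

    def children(self, node_id: str) -> list[str]:
        return list(self._children[node_id])

    def depth(self, node_id: str) -> int:
        return self._depth[node_id]

    def preorder(self) -> list[str]:
        return list(self._preorder)

    def preorder_index(self, node_id: str) -> int:
        return self._preorder_index[node_id]

    def ancestors(self, node_id: str) -> frozenset[str]:
        """Proper ancestors of ``node_id`` (root included, node excluded)."""
        return self._ancestors[node_id]

    def is_proper_ancestor(self, a: str, b: str) -> bool:
        return a in self._ancestors[b]

    def path_from_root(self, node_id: str) -> list[str]:
        path = []
        cur: str | None = node_id
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent_id
        return path[::-1]

    def non_root_ids(self) -> list[str]:
        return [nid for nid in self._preorder if nid != self.root_id]

    def n_non_root(self) -> int:
        return len(self.nodes) - 1

    def has_sizes(self) -> bool:
        return all(self.nodes[nid].size is not None for nid in self.non_root_ids()) and (
            self.n_non_root() > 0
        )

    # -- construction ------------------------------------------------------

    def with_nodes(self, nodes: Sequence[TreeNode]) -> "MutationTree":
        return MutationTree(self.sample_id, nodes, self.clinical)

    def copy_nodes(self) -> list[TreeNode]:
        return [
            TreeNode(n.node_id, n.parent_id, EventSet(n.events.entries),
                     n.matching_label, n.size)
            for n in (self.nodes[nid] for nid in self._preorder)
        ]

    def to_json(self) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "nodes": [self.nodes[nid].to_json() for nid in sorted(self.nodes)]
        }
        if self.clinical:
            doc["clinical"] = dict(sorted(self.clinical.items()))
        return doc

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationTree):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.clinical == other.clinical
            and set(self.nodes) == set(other.nodes)
            and all(
                self.nodes[k].to_json() == other.nodes[k].to_json() for k in self.nodes
            )
        )

    def __repr__(self) -> str:
        return f"MutationTree({self.sample_id!r}, {len(self.nodes)} nodes)"


class DistanceMatrix:
    """Symmetric pairwise distances over an ordered set of sample ids."""

    def __init__(self, sample_ids: Sequence[str], values: np.ndarray):
        self.sample_ids = list(sample_ids)
        self.values = np.asarray(values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} != ({n}, {n})"
            )

    def get(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def reorder(self, order: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in order]
        return DistanceMatrix(list(order), self.values[np.ix_(idx, idx)])

    def to_json(self) -> dict[str, Any]:
        return {
            "sample_ids": list(self.sample_ids),
            "matrix": [[float(v) for v in row] for row in self.values],
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self.sample_ids == other.sample_ids and np.array_equal(
            self.values, other.values
        )


class TreeCohort:
    """Named mutation trees + optional clusters, distances, extras."""

    def __init__(
        self,
        trees: Mapping[str, MutationTree],
        clusters: Sequence[Sequence[str]] | None = None,
        distances: DistanceMatrix | None = None,
        extra: Mapping[str, Any] | None = None,
    ):
        self.trees: dict[str, MutationTree] = dict(trees)
        self.clusters: list[list[str]] | None = (
            None if clusters is None else [list(c) for c in clusters]
        )
        self.distances = distances
        self.extra: dict[str, Any] = dict(extra or {})

    def sample_ids(self) -> list[str]:
        return sorted(self.trees)

    def cluster_of(self, sample_id: str) -> int | None:
        if self.clusters is None:
            return None
        for i, grp in enumerate(self.clusters):
            if sample_id in grp:
                return i
        return None

    def __iter__(self) -> Iterator[MutationTree]:
        for sid in self.sample_ids():
            yield self.trees[sid]

    def __len__(self) -> int:
        return len(self.trees)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TreeCohort):
            return NotImplemented
        return (
            self.trees == other.trees
            and self.clusters == other.clusters
            and self.distances == other.distances
            and self.extra == other.extra
        )


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Violation:
    """One validation failure: where, which rule, human-readable message."""

    path: str
    rule: str
    message: str


def _check_events(ev: Any, path: str, out: list[Violation]) -> None:
    if not isinstance(ev, dict):
        out.append(Violation(path, "events type", "events must be an object"))
        return
    for etype, genes in ev.items():
        epath = f"{path}.{etype}"
        if not isinstance(etype, str) or not etype:
            out.append(Violation(path, "event type token",
                                 "event type must be a non-empty string"))
            continue
        if not isinstance(genes, dict) or not genes:
            out.append(Violation(epath, "empty gene mapping",
                                 f"event type {etype!r} maps to an empty gene mapping"))
            continue
        for gene, detail in genes.items():
            gpath = f"{epath}.{gene}"
            if not isinstance(gene, str) or not gene:
                out.append(Violation(epath, "gene symbol",
                                     "gene symbol must be a non-empty string"))
            if etype in ("amp", "del"):
                if not (isinstance(detail, int) and not isinstance(detail, bool)
                        and detail >= 1):
                    out.append(Violation(
                        gpath, "copy-number detail",
                        f"{etype} detail must be an integer >= 1, got {detail!r}"))
            elif etype == "snv":
                if not isinstance(detail, str):
                    out.append(Violation(gpath, "snv detail",
                                         "snv detail must be a string"))


def _check_tree(sid: str, doc: Any, out: list[Violation]) -> None:
    path = f"trees.{sid}"
    if not isinstance(doc, dict):
        out.append(Violation(path, "tree type", "tree must be an object"))
        return
    nodes = doc.get("nodes")
    if not isinstance(nodes, list) or not nodes:
        out.append(Violation(f"{path}.nodes", "node count",
                             "tree must have a non-empty nodes list"))
        return
    seen: dict[str, dict] = {}
    roots: list[str] = []
    for i, node in enumerate(nodes):
        npath = f"{path}.nodes[{i}]"
        if not isinstance(node, dict):
            out.append(Violation(npath, "node type", "node must be an object"))
            continue
        nid = node.get("node_id")
        if not isinstance(nid, str) or not nid:
            out.append(Violation(npath, "node id",
                                 "node_id must be a non-empty string"))
            continue
        if nid in seen:
            out.append(Violation(npath, "unique node id",
                                 f"duplicate node_id {nid!r}"))
            continue
        seen[nid] = node
        if node.get("parent_id") is None:
            roots.append(nid)
        _check_events(node.get("events", {}), f"{npath}.events", out)
        size = node.get("size")
        if size is not None and (not isinstance(size, (int, float))
                                 or isinstance(size, bool) or size < 0
                                 or not math.isfinite(float(size))):
            out.append(Violation(f"{npath}.size", "size value",
                                 f"size must be a non-negative number, got {size!r}"))
    if len(roots) != 1:
        out.append(Violation(f"{path}.nodes", "single root",
                             f"expected exactly one root node, found {len(roots)}"))
        return
    root_id = roots[0]
    root_events = seen[root_id].get("events", {})
    if isinstance(root_events, dict) and sum(
        len(g) for g in root_events.values() if isinstance(g, dict)
    ) > 0:
        out.append(Violation(f"{path}.nodes", "root events",
                             "root events must be empty (germline state)"))
    # parent references + acyclicity by traversal
    children: dict[str, list[str]] = {nid: [] for nid in seen}
    broken = False
    for nid, node in seen.items():
        pid = node.get("parent_id")
        if pid is None:
            continue
        if pid not in seen:
            out.append(Violation(f"{path}.nodes", "parent reference",
                                 f"node {nid!r} references unknown parent {pid!r}"))
            broken = True
        else:
            children[pid].append(nid)
    if not broken:
        visited = set()
        stack = [root_id]
        while stack:
            cur = stack.pop()
            if cur in visited:
                continue
            visited.add(cur)
            stack.extend(children[cur])
        if len(visited) != len(seen):
            orphans = sorted(set(seen) - visited)
            out.append(Violation(
                f"{path}.nodes", "connectivity",
                f"nodes unreachable from root (cycle or disconnect): {orphans}"))
    # size presence: all non-root or none
    non_root = [nid for nid in seen if nid != root_id]
    with_size = [nid for nid in non_root if seen[nid].get("size") is not None]
    if with_size and len(with_size) != len(non_root):
        missing = sorted(set(non_root) - set(with_size))
        out.append(Violation(f"{path}.nodes", "size presence",
                             f"size present on some non-root nodes but missing on {missing}"))
    clinical = doc.get("clinical")
    if clinical is not None and not isinstance(clinical, dict):
        out.append(Violation(f"{path}.clinical", "clinical type",
                             "clinical must be an object of scalars"))


def _validate_document(doc: Any) -> list[Violation]:
    out: list[Violation] = []
    if not isinstance(doc, dict):
        return [Violation("$", "document type", "top level must be a JSON object")]
    trees = doc.get("trees")
    if not isinstance(trees, dict) or not trees:
        return [Violation("trees", "trees mapping",
                          "document must contain a non-empty 'trees' object")]
    for sid, tree_doc in trees.items():
        _check_tree(sid, tree_doc, out)
    sample_ids = set(trees)

    clusters = doc.get("clusters")
    if clusters is not None:
        if not isinstance(clusters, list) or not all(
            isinstance(c, list) for c in clusters
        ):
            out.append(Violation("clusters", "clusters type",
                                 "clusters must be an array of arrays of sample_ids"))
        else:
            assigned: set[str] = set()
            for i, grp in enumerate(clusters):
                for sid in grp:
                    if sid not in sample_ids:
                        out.append(Violation(
                            f"clusters[{i}]", "cluster membership",
                            f"sample {sid!r} not present in trees"))
                    if sid in assigned:
                        out.append(Violation(
                            f"clusters[{i}]", "cluster disjointness",
                            f"sample {sid!r} appears in two clusters"))
                    assigned.add(sid)

    dist = doc.get("distances")
    if dist is not None:
        if (not isinstance(dist, dict) or "sample_ids" not in dist
                or "matrix" not in dist):
            out.append(Violation("distances", "distances shape",
                                 "distances must contain 'sample_ids' and 'matrix'"))
        else:
            ids = dist["sample_ids"]
            mat = dist["matrix"]
            ok = isinstance(ids, list) and isinstance(mat, list)
            if ok and any(
                not isinstance(row, list) or len(row) != len(ids) for row in mat
            ) or (ok and len(mat) != len(ids)):
                out.append(Violation("distances.matrix", "matrix square",
                                     "matrix not square / not matching sample_ids"))
                ok = False
            if ok:
                arr = None
                try:
                    arr = np.asarray(mat, dtype=float)
                except (TypeError, ValueError):
                    out.append(Violation("distances.matrix", "matrix numeric",
                                         "matrix entries must be numbers"))
                if arr is not None and arr.size:
                    if np.any(arr < 0):
                        out.append(Violation("distances.matrix", "non-negative",
                                             "distances must be non-negative"))
                    if not np.allclose(arr, arr.T, atol=1e-9):
                        out.append(Violation("distances.matrix", "symmetry",
                                             "matrix not symmetric within 1e-9"))
                    if np.any(np.abs(np.diag(arr)) > 1e-12):
                        out.append(Violation("distances.matrix", "zero diagonal",
                                             "diagonal must be zero"))
                if set(ids) != sample_ids:
                    out.append(Violation("distances.sample_ids", "index set",
                                         "distance sample_ids must equal tree sample_ids"))
                if len(set(ids)) != len(ids):
                    out.append(Violation("distances.sample_ids", "unique ids",
                                         "duplicate sample_id in distances"))
    return out


# ---------------------------------------------------------------------------
# Parse / write


def _flatten_nested_nodes(node: dict, parent_id: str | None,
                          acc: list[dict]) -> None:
    flat = {k: v for k, v in node.items() if k != "children"}
    if parent_id is not None:
        flat["parent_id"] = parent_id
    acc.append(flat)
    for child in node.get("children", []):
        _flatten_nested_nodes(child, node.get("node_id"), acc)


def _normalize_tree_doc(tree_doc: Any) -> Any:
    """Accept nested-children node documents; normalize to the flat list."""
    if not isinstance(tree_doc, dict):
        return tree_doc
    nodes = tree_doc.get("nodes")
    if isinstance(nodes, list) and any(
        isinstance(n, dict) and "children" in n for n in nodes
    ):
        flat: list[dict] = []
        for n in nodes:
            if isinstance(n, dict):
                _flatten_nested_nodes(n, n.get("parent_id"), flat)
            else:
                flat.append(n)
        tree_doc = dict(tree_doc)
        tree_doc["nodes"] = flat
    return tree_doc


def _load_document(source: str | Path | dict) -> Any:
    if isinstance(source, dict):
        return source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and not
        source.lstrip().startswith(("{", "["))
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    try:
        return json.loads(text)
    except json.JSONDecodeError as e:
        raise CohortParseError(
            f"malformed JSON at line {e.lineno}, column {e.colno}: {e.msg}"
        ) from e


def validate_cohort(source: str | Path | dict) -> list[Violation]:
    """Collect all format violations; empty list iff :func:`parse_cohort` succeeds.

    Never raises on content errors — only on unreadable sources or
    malformed JSON (which has no document to validate).
    """
    doc = _load_document(source)
    if isinstance(doc, dict) and isinstance(doc.get("trees"), dict):
        doc = dict(doc)
        doc["trees"] = {
            sid: _normalize_tree_doc(td) for sid, td in doc["trees"].items()
        }
    return _validate_document(doc)


def parse_cohort(source: str | Path | dict) -> TreeCohort:
    """Parse and validate a cohort document (path, JSON text, or parsed dict)."""
    doc = _load_document(source)
    if isinstance(doc, dict) and isinstance(doc.get("trees"), dict):
        doc = dict(doc)
        doc["trees"] = {
            sid: _normalize_tree_doc(td) for sid, td in doc["trees"].items()
        }
    violations = _validate_document(doc)
    if violations:
        raise CohortValidationError(violations)

    trees: dict[str, MutationTree] = {}
    for sid, tree_doc in doc["trees"].items():
        nodes = [
            TreeNode(
                node_id=n["node_id"],
                parent_id=n.get("parent_id"),
                events=EventSet(n.get("events", {})),
                matching_label=n.get("matching_label"),
                size=None if n.get("size") is None else float(n["size"]),
            )
            for n in tree_doc["nodes"]
        ]
        trees[sid] = MutationTree(sid, nodes, tree_doc.get("clinical"))

    distances = None
    if doc.get("distances") is not None:
        d = doc["distances"]
        distances = DistanceMatrix(d["sample_ids"], np.asarray(d["matrix"], float))

    known = {"trees", "clusters", "distances"}
    extra = {k: v for k, v in doc.items() if k not in known}
    return TreeCohort(trees, doc.get("clusters"), distances, extra)


def cohort_to_json(cohort: TreeCohort) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "trees": {sid: cohort.trees[sid].to_json() for sid in cohort.sample_ids()}
    }
    if cohort.clusters is not None:
        doc["clusters"] = [list(c) for c in cohort.clusters]
    if cohort.distances is not None:
        doc["distances"] = cohort.distances.to_json()
    doc.update(cohort.extra)
    return doc


def write_cohort(cohort: TreeCohort, dest: str | Path | None = None) -> str:
    """Serialize deterministically (sorted keys); write to ``dest`` if given.

    Returns the JSON text, so ``write_cohort(c)`` also serves as an
    in-memory serializer.  Writing the same cohort twice yields
    byte-identical files.
    """
    text = json.dumps(cohort_to_json(cohort), sort_keys=True, indent=1) + "\n"
    if dest is not None:
        Path(dest).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Distance-matrix TSV dialect: header row and first column hold sample ids


def write_distance_tsv(dm: DistanceMatrix, dest: str | Path | None = None) -> str:
    lines = ["\t" + "\t".join(dm.sample_ids)]
    for sid, row in zip(dm.sample_ids, dm.values):
        lines.append(sid + "\t" + "\t".join(repr(float(v)) for v in row))
    text = "\n".join(lines) + "\n"
    if dest is not None:
        Path(dest).write_text(text, encoding="utf-8")
    return text


def read_distance_tsv(source: str | Path) -> DistanceMatrix:
    text = Path(source).read_text(encoding="utf-8") if (
        isinstance(source, Path) or "\n" not in str(source)
    ) else str(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    ids = header[1:]
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(ids, np.asarray(rows, dtype=float))
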