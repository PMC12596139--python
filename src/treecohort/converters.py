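"""Import mutation trees from inference-tool output tables; export to DOT.

Two generic dialects cover the common encodings used by tree inference
tools: *parent-vector* tables (node_id, parent_id per row; empty parent
marks the root) and *edge-list* tables (parent_id, child_id per row).
Both take a companion events table (node_id, event_type, gene, detail).
Additional tool-specific adapters can be registered by name at run time.

If the declared root itself carries events, an event-free germline root is
inserted above it so that root-to-node profiles stay well-defined.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Callable

import pandas as pd

from .errors import FormatError, StructureError
from .treecore import EventSet, MutationTree, TreeNode
from .treeops import edge_label

__all__ = [
    "convert_parent_vector",
    "convert_edge_list",
    "register_converter",
    "list_converters",
    "get_converter",
    "read_table",
    "to_dot",
    "SYNTHETIC_ROOT_ID",
]

SYNTHETIC_ROOT_ID = "__germline__"

Converter = Callable[..., MutationTree]


def read_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read a TSV/CSV table, sniffing the delimiter from the header line."""
    if isinstance(source, pd.DataFrame):
        return source
    text = Path(source).read_text(encoding="utf-8")
    header = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"{what} table missing required column {col!r}")


def _group_events(
    node_events: pd.DataFrame, known_nodes: set[str]
) -> dict[str, EventSet]:
    _require_columns(node_events, ("node_id", "event_type", "gene", "detail"),
                     "events")
    per_node: dict[str, dict[str, dict[str, object]]] = {}
    for _, row in node_events.iterrows():
        nid = str(row["node_id"])
        if nid not in known_nodes:
            raise StructureError(f"event row references unknown node {nid!r}")
        etype = str(row["event_type"])
        gene = str(row["gene"]).upper()
        detail: object = str(row["detail"])
        if etype in ("amp", "del"):
            try:
                detail = int(detail)
            except ValueError as e:
                raise FormatError(
                    f"{etype} detail for {gene} must be an integer, got {detail!r}"
                ) from e
        per_node.setdefault(nid, {}).setdefault(etype, {})[gene] = detail
    return {nid: EventSet(ev) for nid, ev in per_node.items()}


def _build_tree(
    parent_of: dict[str, str | None], events: dict[str, EventSet], sample_id: str
) -> MutationTree:
    roots = [nid for nid, pid in parent_of.items() if pid is None]
    if len(roots) != 1:
        raise StructureError(
            f"expected exactly one root, found {len(roots)}: {sorted(roots)}"
        )
    root = roots[0]
    if root in events and not events[root].is_empty():
        # source attaches events to its first node: insert germline root
        parent_of = dict(parent_of)
        parent_of[root] = SYNTHETIC_ROOT_ID
        parent_of[SYNTHETIC_ROOT_ID] = None
        root = SYNTHETIC_ROOT_ID
    nodes = [
        TreeNode(nid, pid, events.get(nid, EventSet()))
        for nid, pid in sorted(parent_of.items())
    ]
    try:
        return MutationTree(sample_id, nodes)
    except ValueError as e:
        raise StructureError(str(e)) from e


def convert_parent_vector(
    parents: str | Path | pd.DataFrame,
    node_events: str | Path | pd.DataFrame,
    sample_id: str,
) -> MutationTree:
    """Build a tree from a parent-vector table (empty parent_id = root)."""
    pdf = read_table(parents)
    _require_columns(pdf, ("node_id", "parent_id"), "parent-vector")
    parent_of: dict[str, str | None] = {}
    for _, row in pdf.iterrows():
        nid = str(row["node_id"])
        pid = str(row["parent_id"]).strip()
        if nid in parent_of:
            raise StructureError(f"duplicate node_id {nid!r} in parent vector")
        parent_of[nid] = pid if pid else None
    for nid, pid in parent_of.items():
        if pid is not None and pid not in parent_of:
            raise StructureError(
                f"node {nid!r} references unknown parent {pid!r}"
            )
    events = _group_events(read_table(node_events), set(parent_of))
    return _build_tree(parent_of, events, sample_id)


def convert_edge_list(
    edges: str | Path | pd.DataFrame,
    node_events: str | Path | pd.DataFrame,
    sample_id: str,
) -> MutationTree:
    """Build a tree from an edge-list table (parent_id, child_id per row)."""
    edf = read_table(edges)
    _require_columns(edf, ("parent_id", "child_id"), "edge-list")
    parent_of: dict[str, str | None] = {}
    for _, row in edf.iterrows():
        pid, cid = str(row["parent_id"]), str(row["child_id"])
        if cid in parent_of and parent_of[cid] is not None:
            raise StructureError(f"node {cid!r} has two parents")
        parent_of[cid] = pid
        parent_of.setdefault(pid, None)
    # nodes never seen as children keep parent None; exactly one may remain
    for cid, pid in parent_of.items():
        if pid is not None and pid not in parent_of:
            raise StructureError(f"edge references unknown parent {pid!r}")
    events = _group_events(read_table(node_events), set(parent_of))
    return _build_tree(parent_of, events, sample_id)


_REGISTRY: dict[str, Converter] = {
    "parent_vector": convert_parent_vector,
    "edge_list": convert_edge_list,
}


def register_converter(name: str, func: Converter) -> None:
    if name in _REGISTRY:
        raise ValueError(f"converter {name!r} already registered")
    _REGISTRY[name] = func


def list_converters() -> list[str]:
    return sorted(_REGISTRY)


def get_converter(name: str) -> Converter:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown converter {name!r}; available: {list_converters()}")


def to_dot(tree: MutationTree, *, use_labels: bool = True) -> str:
    """Render a tree as Graphviz DOT text (deterministic node order).

    Node labels show the matching label when present (else the node id);
    edge labels summarize the child's events.  Node sizes, when present,
    are emitted as a ``width`` attribute proportional to sqrt(size).
    """
    lines = [f'digraph "{tree.sample_id}" {{', "  node [shape=circle];"]
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        label = (n.matching_label if (use_labels and n.matching_label) else nid)
        attrs = [f'label="{label}"']
        if n.size is not None:
            attrs.append(f'width="{round(float(n.size) ** 0.5, 4)}"')
        lines.append(f'  "{nid}" [{", ".join(attrs)}];')
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        if n.parent_id is not None:
            elabel = edge_label(n)
            lines.append(f'  "{n.parent_id}" -> "{nid}" [label="{elabel}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
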