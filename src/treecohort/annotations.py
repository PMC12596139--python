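"""Drug–gene interaction lookup and subclone highlighting semantics.

Interactions come from a frozen local TSV snapshot (DGIdb-style: one row
per gene–drug interaction record).  Gene tracking uses a node's *own*
events (which subclone first acquired the mutation); drug impact uses the
accumulated root-to-node mutation profile, so a subclone inherits every
druggable gene of its ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal

import pandas as pd

from .errors import FormatError
from .treecore import EventSet, MutationTree
from .treeops import node_profile

__all__ = [
    "InteractionRecord",
    "InteractionTable",
    "load_interactions",
    "bundled_interactions_path",
    "genes_in_tree",
    "first_acquisition_nodes",
    "drugs_for_gene",
    "nodes_affected_by_drug",
    "highlight_category",
]

REQUIRED_COLUMNS = ("gene", "drug")
OPTIONAL_COLUMNS = ("interaction_type", "source")


@dataclass(frozen=True)
class InteractionRecord:
    gene: str
    drug: str
    interaction_type: str | None = None
    source: str | None = None


class InteractionTable:
    """Deduplicated gene–drug interaction records with gene-indexed lookup."""

    def __init__(self, records: list[InteractionRecord]):
        seen = set()
        unique: list[InteractionRecord] = []
        for r in records:
            if not r.gene or not r.drug:
                raise FormatError("interaction records need non-empty gene and drug")
            key = (r.gene, r.drug, r.interaction_type, r.source)
            if key not in seen:
                seen.add(key)
                unique.append(r)
        self.records = sorted(
            unique, key=lambda r: (r.gene, r.drug, r.interaction_type or "",
                                   r.source or "")
        )
        self._by_gene: dict[str, list[InteractionRecord]] = {}
        self._by_drug: dict[str, list[InteractionRecord]] = {}
        for r in self.records:
            self._by_gene.setdefault(r.gene, []).append(r)
            self._by_drug.setdefault(r.drug, []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def drugs(self) -> list[str]:
        return sorted(self._by_drug)

    def genes_for_drug(self, drug: str) -> set[str]:
        return {r.gene for r in self._by_drug.get(drug, [])}


def load_interactions(source: str | Path) -> InteractionTable:
    """Read an interaction snapshot TSV (columns: gene, drug[, interaction_type, source]).

    Gene symbols are uppercased; fully duplicated rows are dropped.
    """
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"interaction table missing required column {col!r}")
    records = [
        InteractionRecord(
            gene=str(row["gene"]).strip().upper(),
            drug=str(row["drug"]).strip(),
            interaction_type=(str(row["interaction_type"]).strip() or None)
            if "interaction_type" in df.columns else None,
            source=(str(row["source"]).strip() or None)
            if "source" in df.columns else None,
        )
        for _, row in df.iterrows()
        if str(row["gene"]).strip() and str(row["drug"]).strip()
    ]
    return InteractionTable(records)


def bundled_interactions_path() -> Path:
    """Path of the small synthetic interaction fixture shipped with the package."""
    return Path(
        resources.files("treecohort").joinpath("data/interactions_synthetic.tsv")
    )


def genes_in_tree(tree: MutationTree) -> list[str]:
    """Sorted union of genes affected by events anywhere in the tree."""
    genes: set[str] = set()
    for nid in tree.non_root_ids():
        genes.update(tree.nodes[nid].events.genes())
    return sorted(genes)


def first_acquisition_nodes(tree: MutationTree, gene: str) -> list[str]:
    """Nodes that first acquired an event in ``gene`` on their branch.

    A node qualifies when its own event set contains the gene and no
    proper ancestor's does; parallel branches can each contribute one.
    """
    gene = gene.upper()
    carriers = {
        nid for nid in tree.non_root_ids()
        if gene in tree.nodes[nid].events.genes()
    }
    return sorted(
        nid for nid in carriers
        if not (tree.ancestors(nid) & carriers)
    )


def drugs_for_gene(table: InteractionTable, gene: str) -> list[str]:
    """Distinct drugs interacting with ``gene`` (case-insensitive), sorted."""
    return sorted({r.drug for r in table._by_gene.get(gene.upper(), [])})


def nodes_affected_by_drug(
    tree: MutationTree, table: InteractionTable, drug: str
) -> list[str]:
    """Subclones whose accumulated mutation profile carries a gene the drug
    interacts with.

    Because profiles accumulate along the root path, the affected set is
    downward-closed: every descendant of an affected node is affected.
    """
    targets = table.genes_for_drug(drug)
    if not targets:
        return []
    return sorted(
        nid for nid in tree.non_root_ids()
        if node_profile(tree, nid).accumulated.genes() & targets
    )


def highlight_category(
    node_events: EventSet, gene: str
) -> Literal["amplification", "deletion", "other", "none"]:
    """Display category for a gene within a node's own events.

    Priority amplification > deletion > other; ``none`` when the gene is
    not affected in this node.
    """
    gene = gene.upper()
    types = node_events.types_for_gene(gene)
    if not types:
        return "none"
    if "amp" in types:
        return "amplification"
    if "del" in types:
        return "deletion"
    return "other"
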