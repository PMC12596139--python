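"""Seeded synthetic mutation-tree cohort generator.

Emulates clone-level cohorts as produced by mutation tree inference: each
cluster has a base evolutionary history (a random tree with random event
sets) and its member trees are noisy variants of it (leaf insertions,
leaf deletions, event-set replacements).  Cluster 1 additionally carries a
*planted* conserved trajectory — a chain of event-identical nodes on a
root path of every member tree — providing ground truth for trajectory
recovery.  No sequencing noise or read counts are simulated; trees are
generated directly at the subclone level.

Identical seeds reproduce byte-identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .treecore import EventSet, MutationTree, TreeCohort, TreeNode
from .treeops import assign_matching_labels, canonical_label

__all__ = ["SimulationConfig", "simulate_cohort", "perturb_tree"]

logger = logging.getLogger(__name__)

EVENT_TYPES = ("snv", "amp", "del")


def default_gene_pool(n: int = 50) -> list[str]:
    """Synthetic gene symbols G001..G0NN; large enough that chance matches
    across clusters are rare."""
    return [f"G{i:03d}" for i in range(1, n + 1)]


@dataclass
class SimulationConfig:
    n_clusters: int = 3
    trees_per_cluster: int = 4
    nodes_min: int = 5
    nodes_max: int = 8
    gene_pool: list[str] = field(default_factory=default_gene_pool)
    events_per_node_mean: float = 1.5
    perturbations_per_tree: int = 2
    planted_chain_length: int = 3
    clinical_keys: tuple[str, ...] = ("sex", "stage")
    with_sizes: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1 or self.trees_per_cluster < 1:
            raise ValueError("need at least one cluster and one tree per cluster")
        if self.nodes_min < 2 or self.nodes_min > self.nodes_max:
            raise ValueError("need 2 <= nodes_min <= nodes_max")
        if self.planted_chain_length > self.nodes_min:
            raise ValueError("planted_chain_length must be <= nodes_min")
        if self.planted_chain_length < 0 or self.perturbations_per_tree < 0:
            raise ValueError("counts must be non-negative")
        if self.events_per_node_mean <= 0:
            raise ValueError("events_per_node_mean must be positive")
        if not self.gene_pool:
            raise ValueError("gene pool must be non-empty")

    @classmethod
    def from_json(cls, doc: dict[str, Any]) -> "SimulationConfig":
        cfg = cls(**{k: v for k, v in doc.items()})
        if isinstance(cfg.clinical_keys, list):
            cfg.clinical_keys = tuple(cfg.clinical_keys)
        cfg.validate()
        return cfg


_CLINICAL_VOCAB = {
    "sex": ["F", "M"],
    "stage": ["I", "II", "III", "IV"],
}


def _random_events(rng: np.random.Generator, cfg: SimulationConfig) -> EventSet:
    n = max(1, int(rng.poisson(cfg.events_per_node_mean)))
    n = min(n, len(cfg.gene_pool))
    genes = [cfg.gene_pool[i] for i in sorted(
        rng.choice(len(cfg.gene_pool), size=n, replace=False)
    )]
    entries: dict[str, dict[str, Any]] = {}
    for gene in genes:
        etype = EVENT_TYPES[int(rng.integers(len(EVENT_TYPES)))]
        if etype == "snv":
            detail: Any = f"p.V{int(rng.integers(1, 900))}X"
        else:
            detail = int(rng.integers(1, 4))
        entries.setdefault(etype, {})[gene] = detail
    return EventSet(entries)


def _grow_base_tree(
    rng: np.random.Generator, cfg: SimulationConfig, chain_events: list[EventSet]
) -> tuple[list[TreeNode], list[str]]:
    """Random tree by uniform attachment; ``chain_events`` forced onto a
    root path first.  Returns (nodes, chain node ids)."""
    n_nodes = int(rng.integers(cfg.nodes_min, cfg.nodes_max + 1))
    nodes = [TreeNode("r", None, EventSet())]
    chain_ids: list[str] = []
    parent = "r"
    for i, ev in enumerate(chain_events):
        nid = f"n{i + 1}"
        nodes.append(TreeNode(nid, parent, EventSet(ev.entries)))
        chain_ids.append(nid)
        parent = nid
    while len(nodes) - 1 < n_nodes:
        nid = f"n{len(nodes)}"
        attach = nodes[int(rng.integers(len(nodes)))].node_id
        nodes.append(TreeNode(nid, attach, _random_events(rng, cfg)))
    if cfg.with_sizes:
        for n in nodes[1:]:
            n.size = round(float(rng.uniform(0.05, 1.0)), 4)
    return nodes, chain_ids


def _apply_perturbations(
    rng: np.random.Generator,
    tree: MutationTree,
    n_ops: int,
    cfg: SimulationConfig,
    protected: frozenset[str],
) -> MutationTree:
    nodes = {n.node_id: n for n in tree.copy_nodes()}
    fresh = 0
    for _ in range(n_ops):
        op = int(rng.integers(3))
        if op == 0:  # leaf insertion
            fresh += 1
            attach = sorted(nodes)[int(rng.integers(len(nodes)))]
            nid = f"p{fresh}"
            while nid in nodes:
                fresh += 1
                nid = f"p{fresh}"
            size = round(float(rng.uniform(0.05, 1.0)), 4) if cfg.with_sizes else None
            nodes[nid] = TreeNode(nid, attach, _random_events(rng, cfg), None, size)
        elif op == 1:  # leaf deletion
            parents = {n.parent_id for n in nodes.values() if n.parent_id}
            leaves = sorted(
                nid for nid, n in nodes.items()
                if nid not in parents and n.parent_id is not None
                and nid not in protected
            )
            if not leaves or len(nodes) <= 2:
                logger.warning("perturbation skipped: no deletable leaf")
                continue
            del nodes[leaves[int(rng.integers(len(leaves)))]]
        else:  # event-set replacement
            candidates = sorted(
                nid for nid, n in nodes.items()
                if n.parent_id is not None and nid not in protected
            )
            if not candidates:
                logger.warning("perturbation skipped: no replaceable node")
                continue
            nid = candidates[int(rng.integers(len(candidates)))]
            n = nodes[nid]
            nodes[nid] = TreeNode(nid, n.parent_id, _random_events(rng, cfg),
                                  None, n.size)
    return MutationTree(tree.sample_id, list(nodes.values()), tree.clinical)


def perturb_tree(
    tree: MutationTree, n_ops: int, seed: int,
    *, protected: frozenset[str] = frozenset(),
    config: SimulationConfig | None = None,
) -> MutationTree:
    """Apply ``n_ops`` random structural/event perturbations (seeded).

    Operations: leaf insertion, leaf deletion, event-set replacement.
    ``n_ops=0`` returns a structurally equal copy; deletions that would
    leave fewer than two nodes are skipped with a warning.
    """
    if n_ops < 0:
        raise ValueError("n_ops must be >= 0")
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    return _apply_perturbations(rng, tree, n_ops, cfg, protected)


def _clinical(rng: np.random.Generator, cfg: SimulationConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key in cfg.clinical_keys:
        vocab = _CLINICAL_VOCAB.get(key, ["A", "B", "C"])
        out[key] = vocab[int(rng.integers(len(vocab)))]
    return out


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[TreeCohort, dict[str, Any]]:
    """Generate a clustered cohort plus its ground-truth record.

    Per cluster, one base tree is grown by uniform random attachment and
    each member is a perturbed copy of it.  Cluster 1 (index 0) carries
    the planted conserved chain on a root path of every member tree;
    planted nodes are protected from deletion/replacement so the chain is
    guaranteed by construction.  Matching labels are assigned canonically.
    Returns ``(cohort, truth)`` where truth records clusters and the
    planted chain's labels.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    trees: dict[str, MutationTree] = {}
    clusters: list[list[str]] = []
    planted_labels: list[str] = []

    for ci in range(cfg.n_clusters):
        chain_events: list[EventSet] = []
        if ci == 0 and cfg.planted_chain_length > 0:
            chain_events = [
                _random_events(rng, cfg) for _ in range(cfg.planted_chain_length)
            ]
            planted_labels = [canonical_label(ev) for ev in chain_events]
        base_nodes, chain_ids = _grow_base_tree(rng, cfg, chain_events)
        protected = frozenset(chain_ids)
        group: list[str] = []
        for ti in range(cfg.trees_per_cluster):
            sid = f"c{ci + 1}_t{ti + 1}"
            base = MutationTree(sid, [
                TreeNode(n.node_id, n.parent_id, EventSet(n.events.entries),
                         None, n.size)
                for n in base_nodes
            ], _clinical(rng, cfg))
            tree = _apply_perturbations(
                rng, base, cfg.perturbations_per_tree, cfg, protected
            )
            trees[sid] = tree
            group.append(sid)
        clusters.append(group)

    cohort = assign_matching_labels(TreeCohort(trees, clusters))
    truth = {
        "seed": cfg.seed,
        "clusters": clusters,
        "planted_chain_labels": planted_labels,
        "planted_cluster": 0 if planted_labels else None,
    }
    return cohort, truth
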