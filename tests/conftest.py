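from __future__ import annotations

import json

import pytest

from treecohort.simulate import SimulationConfig, simulate_cohort
from treecohort.treecore import EventSet, MutationTree, TreeCohort, TreeNode
from treecohort.treeops import assign_matching_labels


def build_tree(sample_id: str, rows: list[tuple], clinical=None) -> MutationTree:
    """Tiny tree builder: rows are (node_id, parent_id, events[, label[, size]])."""
    nodes = []
    for row in rows:
        nid, pid, events = row[0], row[1], row[2]
        label = row[3] if len(row) > 3 else None
        size = row[4] if len(row) > 4 else None
        nodes.append(TreeNode(nid, pid, EventSet(events), label, size))
    return MutationTree(sample_id, nodes, clinical)


def labeled_chain(sample_id: str, labels: list[str]) -> MutationTree:
    """Chain root -> l1 -> l2 -> ... with explicit matching labels."""
    rows: list[tuple] = [("r", None, {})]
    parent = "r"
    for i, lbl in enumerate(labels):
        nid = f"n{i}"
        rows.append((nid, parent, {"snv": {f"GENE{lbl}": ""}}, lbl))
        parent = nid
    return build_tree(sample_id, rows)


@pytest.fixture
def minimal_doc() -> dict:
    return {
        "trees": {
            "s1": {
                "nodes": [
                    {"node_id": "r", "events": {}},
                    {"node_id": "n1", "parent_id": "r",
                     "events": {"snv": {"TP53": "p.R175H"}}},
                ]
            }
        }
    }


@pytest.fixture
def minimal_json(minimal_doc) -> str:
    return json.dumps(minimal_doc)


@pytest.fixture
def sim_cohort():
    cohort, truth = simulate_cohort(SimulationConfig(seed=42))
    return cohort, truth


@pytest.fixture
def labeled_cohort(sim_cohort) -> TreeCohort:
    return sim_cohort[0]


def make_labeled_cohort(trees: list[MutationTree], clusters=None) -> TreeCohort:
    return assign_matching_labels(
        TreeCohort({t.sample_id: t for t in trees}, clusters)
    )
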