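"""Shared fixtures: hand-built DAGs, the published worked example, and
seeded synthetic ontologies/corpora."""

from __future__ import annotations

import pytest

from wissim import (
    OntologyGraph,
    Term,
    WeightedEdgeTable,
    generate_synthetic_corpus,
    generate_synthetic_ontology,
)


def make_graph(edges, namespace="biological_process"):
    """Build an OntologyGraph from (child, parent[, relation]) tuples."""
    triples = [
        (e[0], e[1], e[2] if len(e) > 2 else "is_a") for e in edges
    ]
    ids = sorted({x for e in triples for x in e[:2]})
    terms = [Term(id=t, namespace=namespace) for t in ids]
    return OntologyGraph(terms, triples)


@pytest.fixture
def chain3():
    """r -> a -> b."""
    return make_graph([("a", "r"), ("b", "a")])


@pytest.fixture
def diamond():
    """r with children a, c; a -> c makes depth(c) = 2 by longest path."""
    return make_graph([("a", "r"), ("c", "r"), ("c", "a")])


@pytest.fixture(scope="session")
def random_dag():
    return generate_synthetic_ontology(200, max_depth=6, max_parents=3, seed=7)


@pytest.fixture(scope="session")
def random_corpus(random_dag):
    return generate_synthetic_corpus(
        random_dag, n_genes=40, terms_per_gene=(2, 5), iea_fraction=0.3, seed=11
    )


# ---------------------------------------------------------------------------
# The published seven-term worked example: a DAG with printed edge weights and
# per-step extended-IC increments.  Term ICs are recovered by solving each
# printed step equation in order (an inversion oracle, independent of set_ic).
# ---------------------------------------------------------------------------

WORKED_EDGES = [
    ("t2", "t1"), ("t3", "t1"), ("t4", "t2"), ("t6", "t4"),
    ("t6", "t3"), ("t5", "t3"), ("t7", "t6"), ("t7", "t5"),
]
WORKED_WEIGHTS = {
    ("t2", "t1"): 0.80, ("t3", "t1"): 0.46, ("t4", "t2"): 0.57,
    ("t6", "t4"): 0.71, ("t6", "t3"): 0.92, ("t5", "t3"): 0.70,
    ("t7", "t6"): 0.73, ("t7", "t5"): 0.96,
}
# Printed per-step extended-IC increments in insertion order t1..t7.
WORKED_INCREMENTS = [0.0, 0.003, 0.011, 0.010, 0.012, 0.012, 0.003]
WORKED_TOTAL = 0.051


def invert_worked_example_ics():
    """Solve the printed step equations in order to recover each term's IC."""
    w = WORKED_WEIGHTS
    ic = {"t1": 0.0}
    ic["t2"] = WORKED_INCREMENTS[1] + w[("t2", "t1")] * ic["t1"]
    ic["t3"] = WORKED_INCREMENTS[2] + w[("t3", "t1")] * ic["t1"]
    ic["t4"] = WORKED_INCREMENTS[3] + w[("t4", "t2")] * ic["t2"]
    ic["t5"] = WORKED_INCREMENTS[4] + w[("t5", "t3")] * ic["t3"]
    ic["t6"] = (
        WORKED_INCREMENTS[5]
        + w[("t6", "t4")] * ic["t4"]
        + w[("t6", "t3")] * ic["t3"]
    )
    ic["t7"] = (
        WORKED_INCREMENTS[6]
        + w[("t7", "t6")] * ic["t6"]
        + w[("t7", "t5")] * ic["t5"]
    )
    return ic


@pytest.fixture(scope="session")
def worked_example():
    graph = make_graph(WORKED_EDGES)
    weights = WeightedEdgeTable(dict(WORKED_WEIGHTS))
    return graph, weights, invert_worked_example_ics()
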