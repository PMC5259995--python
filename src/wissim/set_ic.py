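"""Information content of a term set via weighted inherited semantics.

A term inherits part of its semantics from its parents.  When summing IC over
a term set, adding each term's full IC double-counts what it shares with
parents already in the set.  The accumulation implemented here splits each
term's IC into an inherited part, weighted per edge, and an extended part
unique to the term, and only the extended part is added:

* edge weight  ``omega(child, parent) = Dst(child) / Dst(parent)`` where
  ``Dst`` counts descendants (including the term itself) in the *whole*
  namespace graph — so ``0 < omega < 1`` for every edge;
* extended IC of a term against the parents already present:
  ``IC(t) - sum_p omega(t, p) * IC(p)``;
* set IC: process the (ancestor-closed) set in topological order, summing
  extended ICs.

With unit weights (``weighting="unit"``) the scheme degenerates to full
inheritance: along a chain the contributions telescope to the deepest term's
IC.  With multiple high-weight parents the extended IC can go negative;
flooring it at 0 (the default) keeps set ICs monotone under set inclusion and
similarity ratios inside [0, 1], while ``floor=False`` preserves the literal
arithmetic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .ontology import OntologyGraph
from .term_ic import ICTable

logger = logging.getLogger(__name__)

WEIGHTINGS = ("wis", "unit")


@dataclass
class WeightedEdgeTable:
    """Inheritance weight omega for every (child, parent) edge of a graph."""

    weights: dict[tuple[str, str], float]
    fingerprint: str = ""

    def __getitem__(self, edge: tuple[str, str]) -> float:
        return self.weights[edge]

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.weights

    def __len__(self) -> int:
        return len(self.weights)

    def write_tsv(self, graph: OntologyGraph, path: str | Path) -> None:
        lines = ["child\tparent\trelation\tomega"]
        for (c, p), w in sorted(self.weights.items()):
            lines.append(f"{c}\t{p}\t{graph.relation(c, p)}\t{w:.12g}")
        Path(path).write_text("\n".join(lines) + "\n")


def edge_weight(g: OntologyGraph, child: str, parent: str) -> float:
    """Descendant-count ratio for one edge, strictly inside (0, 1)."""
    if parent not in g.parents(child):
        raise KeyError(f"({child}, {parent}) is not an edge of the graph")
    return g.descendant_count(child) / g.descendant_count(parent)


def compute_edge_weights(g: OntologyGraph) -> WeightedEdgeTable:
    """Tabulate omega for every edge of the graph."""
    weights = {
        (c, p): g.descendant_count(c) / g.descendant_count(p)
        for c, p, _rel in g.edges()
    }
    fingerprint = f"terms={len(g)},edges={len(weights)}"
    return WeightedEdgeTable(weights, fingerprint)


def extended_ic(
    ic: ICTable | Mapping[str, float],
    weights: WeightedEdgeTable,
    t: str,
    present_parents: Iterable[str],
    floor: bool = True,
    unit_weights: bool = False,
) -> float:
    """IC of ``t`` minus the weighted IC inherited from the given parents.

    ``present_parents`` must be graph parents of ``t`` (an edge must exist in
    the weight table).  A term with no present parents contributes its full
    IC.  With ``floor`` the contribution is clamped at 0.
    """
    value = ic[t]
    for p in present_parents:
        if (t, p) not in weights:
            raise KeyError(f"{p} is not a graph parent of {t}")
        omega = 1.0 if unit_weights else weights[(t, p)]
        value -= omega * ic[p]
    if floor and value < 0.0:
        value = 0.0
    return value


@dataclass
class TermSetIC:
    """Result of the set-IC accumulation, with a per-term audit trail."""

    terms: tuple[str, ...]
    total: float
    contributions: dict[str, float] = field(default_factory=dict)
    floored: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total": self.total,
            "floored": self.floored,
            "contributions": dict(sorted(self.contributions.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def set_ic(
    ic: ICTable | Mapping[str, float],
    weights: WeightedEdgeTable,
    g: OntologyGraph,
    terms: Iterable[str],
    floor: bool = True,
    weighting: str = "wis",
) -> TermSetIC:
    """Accumulate the IC of a term set in topological order.

    The set is ancestor-closed first (with a log notice if terms had to be
    added), then each term contributes its extended IC against the parents
    already in the set.  ``weighting="unit"`` substitutes omega = 1 on every
    edge (full, unweighted inheritance).
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    term_set = set(terms)
    if not term_set:
        raise ValueError("term set is empty")
    closed = g.ancestor_closure(term_set)
    if closed != term_set:
        logger.info(
            "set_ic input was not ancestor-closed; added %d ancestors",
            len(closed) - len(term_set),
        )
    order = [t for t in g.topological_order() if t in closed]
    unit = weighting == "unit"
    contributions: dict[str, float] = {}
    total = 0.0
    for t in order:
        present = [p for p in g.parents(t) if p in closed]
        contrib = extended_ic(ic, weights, t, present, floor=floor, unit_weights=unit)
        contributions[t] = contrib
        total += contrib
    return TermSetIC(tuple(order), total, contributions, floored=floor)


def set_ic_oracle(
    ic: ICTable | Mapping[str, float],
    weights: WeightedEdgeTable,
    g: OntologyGraph,
    terms: Iterable[str],
    weighting: str = "wis",
) -> float:
    """Closed-form total for an ancestor-closed set (no incremental loop).

    ``sum_{t in S} IC(t) - sum_{edges (t -> p) inside S} omega * IC(p)``;
    equals ``set_ic`` with flooring off.  Used as an independent cross-check
    of the accumulation.
    """
    term_set = g.ancestor_closure(set(terms))
    if not term_set:
        raise ValueError("term set is empty")
    unit = weighting == "unit"
    total = sum(ic[t] for t in term_set)
    for t in term_set:
        for p in g.parents(t):
            if p in term_set:
                omega = 1.0 if unit else weights[(t, p)]
                total -= omega * ic[p]
    return total
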