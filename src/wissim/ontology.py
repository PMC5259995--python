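"""Ontology graphs, annotation corpora and synthetic fixtures.

The Gene Ontology is three rooted directed acyclic graphs (biological_process,
molecular_function, cellular_component) whose nodes are terms and whose edges
(is_a, part_of) point from a child term to its more general parents.  This
module loads OBO ontologies and GAF annotation files, answers the structural
queries every information-content model needs (ancestors, descendants, depth,
topological order), and generates seeded synthetic ontologies and annotation
corpora so the whole pipeline can be exercised without network access.

Conventions
-----------
* Edges are stored child -> parent (towards the root).
* ``depth`` is the length of the *longest* path from the namespace root, with
  ``depth(root) = 0``.  The longest-path convention honours a term's most
  specific placement and makes depth strictly increase along every edge.
* Namespaces are independent: every structural query stays inside the
  namespace of its argument term.
* All orderings break ties lexicographically on term id, so results are
  deterministic.
"""

from __future__ import annotations

import heapq
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}
NAMESPACE_TO_ASPECT = {v: k for k, v in ASPECT_TO_NAMESPACE.items()}
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass(frozen=True)
class Term:
    """A single ontology term."""

    id: str
    name: str = ""
    namespace: str = "biological_process"
    obsolete: bool = False


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene -> term annotation with its evidence code and aspect letter."""

    gene: str
    term: str
    evidence: str = "IDA"
    aspect: str = "P"


class OntologyGraph:
    """A rooted DAG of terms with typed child -> parent edges.

    Parameters
    ----------
    terms:
        The (non-obsolete) terms of the ontology.
    edges:
        Triples ``(child_id, parent_id, relation)`` with relation in
        ``{"is_a", "part_of"}``.
    alt_ids:
        Mapping of secondary term ids to primary ids, used when resolving
        annotation files.
    """

    def __init__(
        self,
        terms: Iterable[Term],
        edges: Iterable[tuple[str, str, str]],
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self._terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self._terms:
                raise ValueError(f"duplicate term id {t.id}")
            self._terms[t.id] = t
        self.alt_ids: dict[str, str] = dict(alt_ids or {})

        # child -> parent digraph; a duplicate (child, parent) pair keeps the
        # first relation seen (is_a before part_of in OBO files).
        self._g = nx.DiGraph()
        self._g.add_nodes_from(self._terms)
        for child, parent, relation in edges:
            if child == parent:
                raise ValueError(f"self-edge on {child}")
            for endpoint in (child, parent):
                if endpoint not in self._terms:
                    raise ValueError(f"edge endpoint {endpoint} is not a known term")
            if self._terms[child].namespace != self._terms[parent].namespace:
                raise ValueError(
                    f"edge {child} -> {parent} crosses namespaces"
                )
            if not self._g.has_edge(child, parent):
                self._g.add_edge(child, parent, relation=relation)

        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")

        self._roots: dict[str, str] = {}
        for tid, term in self._terms.items():
            if self._g.out_degree(tid) == 0:
                ns = term.namespace
                if ns in self._roots:
                    raise ValueError(
                        f"namespace {ns} has multiple roots: "
                        f"{self._roots[ns]}, {tid}"
                    )
                self._roots[ns] = tid

        self._depth: dict[str, int] | None = None
        self._topo: list[str] | None = None
        self._desc_count: dict[str, int] | None = None
        self._anc_sets: dict[str, frozenset[str]] | None = None
        self._desc_sets: dict[str, frozenset[str]] | None = None

    # -- basic accessors ---------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    @property
    def terms(self) -> dict[str, Term]:
        return self._terms

    @property
    def roots(self) -> dict[str, str]:
        """Designated root term per namespace."""
        return dict(self._roots)

    @property
    def namespaces(self) -> list[str]:
        return sorted(self._roots)

    def term_ids(self, namespace: str | None = None) -> list[str]:
        if namespace is None:
            return sorted(self._terms)
        return sorted(t for t, trm in self._terms.items() if trm.namespace == namespace)

    def namespace_of(self, term_id: str) -> str:
        self._check(term_id)
        return self._terms[term_id].namespace

    def root_of(self, term_id: str) -> str:
        return self._roots[self.namespace_of(term_id)]

    def max_nodes(self, namespace: str) -> int:
        """Total number of (non-obsolete) terms in a namespace."""
        return len(self.term_ids(namespace))

    def edges(self) -> list[tuple[str, str, str]]:
        """All ``(child, parent, relation)`` triples, sorted."""
        return sorted(
            (c, p, d["relation"]) for c, p, d in self._g.edges(data=True)
        )

    def parents(self, term_id: str) -> list[str]:
        self._check(term_id)
        return sorted(self._g.successors(term_id))

    def children(self, term_id: str) -> list[str]:
        self._check(term_id)
        return sorted(self._g.predecessors(term_id))

    def relation(self, child: str, parent: str) -> str:
        if not self._g.has_edge(child, parent):
            raise KeyError(f"({child}, {parent}) is not an edge")
        return self._g.edges[child, parent]["relation"]

    def _check(self, term_id: str) -> None:
        if term_id not in self._terms:
            raise KeyError(f"unknown term {term_id}")

    # -- structural queries ------------------------------------------------

    def ancestors(self, term_id: str, include_self: bool = False) -> set[str]:
        """Transitive closure of parents of ``term_id``."""
        self._check(term_id)
        if self._anc_sets is None:
            # One dynamic-programming pass over the topological order; the
            # per-term sets are reused by every IC model and edge weight.
            sets: dict[str, frozenset[str]] = {}
            for tid in self.topological_order():
                acc: set[str] = set()
                for p in self._g.successors(tid):
                    acc.add(p)
                    acc |= sets[p]
                sets[tid] = frozenset(acc)
            self._anc_sets = sets
        result = set(self._anc_sets[term_id])
        if include_self:
            result.add(term_id)
        return result

    def descendants(self, term_id: str, include_self: bool = False) -> set[str]:
        """Transitive closure of children of ``term_id``."""
        self._check(term_id)
        if self._desc_sets is None:
            sets: dict[str, frozenset[str]] = {}
            for tid in reversed(self.topological_order()):
                acc: set[str] = set()
                for c in self._g.predecessors(tid):
                    acc.add(c)
                    acc |= sets[c]
                sets[tid] = frozenset(acc)
            self._desc_sets = sets
        result = set(self._desc_sets[term_id])
        if include_self:
            result.add(term_id)
        return result

    def is_leaf(self, term_id: str) -> bool:
        self._check(term_id)
        return self._g.in_degree(term_id) == 0

    def leaves(self, namespace: str) -> list[str]:
        return [t for t in self.term_ids(namespace) if self.is_leaf(t)]

    def depth(self, term_id: str) -> int:
        """Longest-path distance from the namespace root; root has depth 0."""
        self._check(term_id)
        if self._depth is None:
            depth: dict[str, int] = {}
            for tid in self.topological_order():
                ps = self.parents(tid)
                depth[tid] = 0 if not ps else 1 + max(depth[p] for p in ps)
            self._depth = depth
        return self._depth[term_id]

    def topological_order(self, namespace: str | None = None) -> list[str]:
        """Terms ordered parents-first; ties broken by term id."""
        if self._topo is None:
            # Kahn's algorithm over parent -> child direction with a heap.
            indeg = {t: self._g.out_degree(t) for t in self._terms}
            ready = [t for t, d in indeg.items() if d == 0]
            heapq.heapify(ready)
            order: list[str] = []
            while ready:
                t = heapq.heappop(ready)
                order.append(t)
                for child in self._g.predecessors(t):
                    indeg[child] -= 1
                    if indeg[child] == 0:
                        heapq.heappush(ready, child)
            if len(order) != len(self._terms):  # pragma: no cover - guarded in init
                raise ValueError("graph contains a cycle")
            self._topo = order
        if namespace is None:
            return list(self._topo)
        return [t for t in self._topo if self._terms[t].namespace == namespace]

    def ancestor_closure(self, term_ids: Iterable[str]) -> set[str]:
        """The given terms together with all of their ancestors."""
        closed: set[str] = set()
        for t in term_ids:
            self._check(t)
            closed.add(t)
            closed |= self.ancestors(t)
        return closed

    def descendant_count(self, term_id: str) -> int:
        """Number of descendants of a term *including the term itself*.

        Counted on the whole namespace graph; used both by the structural IC
        models and by the edge inheritance weights.
        """
        self._check(term_id)
        if self._desc_count is None:
            self._desc_count = {
                t: len(self.descendants(t, include_self=True)) for t in self._terms
            }
        return self._desc_count[term_id]

    def leaf_descendant_count(self, term_id: str) -> int:
        """Number of leaf descendants of a term, excluding the term itself."""
        self._check(term_id)
        return sum(1 for d in self.descendants(term_id) if self.is_leaf(d))


# ---------------------------------------------------------------------------
# OBO / GAF input-output
# ---------------------------------------------------------------------------


def load_obo(
    path: str | Path,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> OntologyGraph:
    """Load an OBO 1.2/1.4 ontology restricted to the requested relations.

    Obsolete terms are excluded; ``alt_id`` mappings are retained on the
    returned graph so annotations to secondary ids can be resolved.
    """
    relations = frozenset(relations)
    unknown = relations - DEFAULT_RELATIONS
    if unknown:
        raise ValueError(f"unsupported relations requested: {sorted(unknown)}")

    mdg = obonet.read_obo(str(path), ignore_obsolete=True)
    terms = []
    alt_ids: dict[str, str] = {}
    for tid, data in mdg.nodes(data=True):
        terms.append(
            Term(
                id=tid,
                name=data.get("name", ""),
                namespace=data.get("namespace", "biological_process"),
            )
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = tid
    edges = [
        (child, parent, key)
        for child, parent, key in mdg.edges(keys=True)
        if key in relations
    ]
    return OntologyGraph(terms, edges, alt_ids=alt_ids)


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Write an ontology as a minimal OBO 1.2 file (round-trips via load_obo)."""
    lines = ["format-version: 1.2", "ontology: wissim-synthetic", ""]
    for tid in graph.term_ids():
        term = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {term.name or tid}")
        lines.append(f"namespace: {term.namespace}")
        for parent in graph.parents(tid):
            rel = graph.relation(tid, parent)
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


class GeneAnnotationSet:
    """Gene -> directly annotated term ids, with the evidence filter applied.

    Only genes with at least one retained term are kept.  Terms are
    de-duplicated; annotations to alt_ids are mapped to primary ids and
    annotations to unknown/obsolete terms are dropped with a logged count.
    """

    def __init__(
        self,
        records: Iterable[AnnotationRecord],
        graph: OntologyGraph | None = None,
        provenance: str = "",
    ) -> None:
        self.provenance = provenance
        self.records: list[AnnotationRecord] = []
        direct: dict[str, set[str]] = {}
        dropped = 0
        for rec in records:
            term = rec.term
            if graph is not None:
                if term not in graph and term in graph.alt_ids:
                    term = graph.alt_ids[term]
                if term not in graph:
                    dropped += 1
                    continue
            self.records.append(
                AnnotationRecord(rec.gene, term, rec.evidence, rec.aspect)
            )
            direct.setdefault(rec.gene, set()).add(term)
        if dropped:
            logger.info("dropped %d annotations to unknown/obsolete terms", dropped)
        self._direct = direct

    @property
    def genes(self) -> list[str]:
        return sorted(self._direct)

    def __len__(self) -> int:
        return len(self._direct)

    def __contains__(self, gene: str) -> bool:
        return gene in self._direct

    def terms(self, gene: str) -> frozenset[str]:
        if gene not in self._direct:
            raise KeyError(f"gene {gene} has no annotations")
        return frozenset(self._direct[gene])

    def gene_term_pairs(self) -> list[tuple[str, str]]:
        """De-duplicated (gene, term) pairs, sorted."""
        return sorted(
            (g, t) for g, ts in self._direct.items() for t in ts
        )

    def filtered(self, evidence_filter: str, graph: OntologyGraph | None = None) -> "GeneAnnotationSet":
        """Apply an ``iea+``/``iea-`` evidence filter to the stored records."""
        keep = _evidence_predicate(evidence_filter)
        recs = [r for r in self.records if keep(r.evidence)]
        if not any(recs):
            raise ValueError("evidence filter removed every annotation record")
        return GeneAnnotationSet(
            recs, graph=graph, provenance=f"{self.provenance}|{evidence_filter}"
        )


def _evidence_predicate(evidence_filter: str):
    ef = evidence_filter.lower().replace("_", "").replace(" ", "")
    if ef in ("iea+", "ieaplus", "all"):
        return lambda code: True
    if ef in ("iea-", "ieaminus"):
        return lambda code: code.upper() != "IEA"
    raise ValueError(f"unknown evidence filter {evidence_filter!r}")


def load_gaf(
    path: str | Path,
    aspect: str = "P",
    evidence_filter: str = "iea+",
    graph: OntologyGraph | None = None,
) -> GeneAnnotationSet:
    """Read a GAF 2.x annotation file for one GO aspect.

    ``aspect`` is the GAF column-9 letter (P/F/C) or a namespace name.
    ``evidence_filter`` is ``"iea+"`` (keep everything) or ``"iea-"`` (drop
    records whose evidence code is IEA).  NOT-qualified records are always
    excluded.  Malformed lines are skipped with a logged count.
    """
    if aspect in NAMESPACE_TO_ASPECT:
        aspect = NAMESPACE_TO_ASPECT[aspect]
    if aspect not in ASPECT_TO_NAMESPACE:
        raise ValueError(f"unknown aspect {aspect!r}")
    keep = _evidence_predicate(evidence_filter)

    records: list[AnnotationRecord] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                skipped += 1
                continue
            qualifier, go_id, evidence, asp = cols[3], cols[4], cols[6], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if asp != aspect or not keep(evidence):
                continue
            gene = cols[2] or cols[1]
            if not gene or not go_id:
                skipped += 1
                continue
            records.append(AnnotationRecord(gene, go_id, evidence, asp))
    if skipped:
        logger.info("skipped %d malformed GAF lines", skipped)

    ann = GeneAnnotationSet(
        records, graph=graph, provenance=f"{path}|{aspect}|{evidence_filter}"
    )
    if len(ann) == 0:
        raise ValueError("no genes retained after filtering the GAF file")
    return ann


def write_gaf(annotations: GeneAnnotationSet, path: str | Path) -> None:
    """Write annotation records as a minimal valid GAF 2.2 file."""
    lines = ["!gaf-version: 2.2"]
    for rec in sorted(annotations.records, key=lambda r: (r.gene, r.term)):
        cols = [""] * 17
        cols[0] = "WISSIM"
        cols[1] = rec.gene
        cols[2] = rec.gene
        cols[3] = "involved_in"
        cols[4] = rec.term
        cols[5] = "WISSIM:0000001"
        cols[6] = rec.evidence
        cols[8] = rec.aspect
        cols[11] = "protein"
        cols[12] = "taxon:0"
        cols[13] = "20160101"
        cols[14] = "WISSIM"
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation corpus (for the corpus-based IC model)
# ---------------------------------------------------------------------------


@dataclass
class Corpus:
    """Per-term annotation counts with descendant propagation.

    ``propagated[t]`` sums the direct (gene, term) annotation counts over the
    descendants of ``t`` including ``t`` itself, so the root's propagated count
    equals the total number of de-duplicated gene-term pairs in its namespace.
    """

    direct: dict[str, int]
    propagated: dict[str, int]
    totals: dict[str, int] = field(default_factory=dict)  # per-namespace root totals

    def probability(self, graph: OntologyGraph, term_id: str) -> float:
        """p(t): annotation probability of a term and its descendants."""
        root = graph.root_of(term_id)
        total = self.propagated.get(root, 0)
        if total == 0:
            raise ValueError(f"corpus has no annotations in namespace of {term_id}")
        return self.propagated.get(term_id, 0) / total


def build_corpus(graph: OntologyGraph, annotations: GeneAnnotationSet) -> Corpus:
    """Count annotations per term and propagate them to all ancestors."""
    direct: dict[str, int] = {}
    for _, term in annotations.gene_term_pairs():
        direct[term] = direct.get(term, 0) + 1
    propagated: dict[str, int] = {t: 0 for t in graph.terms}
    # Add each directly annotated term's count to all of its ancestors.
    for term, count in direct.items():
        for anc in graph.ancestors(term, include_self=True):
            propagated[anc] += count
    totals = {ns: propagated[root] for ns, root in graph.roots.items()}
    return Corpus(direct=direct, propagated=propagated, totals=totals)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def generate_synthetic_ontology(
    n_terms: int,
    max_depth: int = 8,
    max_parents: int = 3,
    part_of_fraction: float = 0.2,
    seed: int = 0,
    namespace: str = "biological_process",
) -> OntologyGraph:
    """Generate a seeded single-root DAG that mimics a GO namespace.

    Every non-root term is assigned a layer in ``1..max_depth`` and draws
    between 1 and ``max_parents`` parents from strictly shallower layers, so
    the graph is acyclic by construction.  Relation labels are ``part_of``
    with probability ``part_of_fraction`` and ``is_a`` otherwise.  Output is
    reproducible for a fixed seed.
    """
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    if max_parents < 1 or max_depth < 1:
        raise ValueError("max_parents and max_depth must be >= 1")

    rng = random.Random(seed)
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    root = ids[0]
    layer_of = {root: 0}
    by_layer: dict[int, list[str]] = {0: [root]}
    edges: list[tuple[str, str, str]] = []

    for i, tid in enumerate(ids[1:], start=1):
        # Seed the first max_depth terms one per layer so every layer is
        # reachable; later terms pick a populated layer at random.
        if i <= max_depth:
            layer = i
        else:
            layer = rng.randint(1, max_depth)
        deepest_populated = max(l for l in by_layer if l < layer)
        pool = [t for l, ts in by_layer.items() if l < layer for t in ts]
        n_parents = min(rng.randint(1, max_parents), len(pool))
        # Anchor to the deepest populated shallower layer so depth == layer.
        first = rng.choice(by_layer[deepest_populated])
        others = [t for t in pool if t != first]
        rng.shuffle(others)
        parents = [first] + others[: n_parents - 1]
        for p in sorted(parents):
            rel = "part_of" if rng.random() < part_of_fraction else "is_a"
            edges.append((tid, p, rel))
        layer_of[tid] = layer
        by_layer.setdefault(layer, []).append(tid)

    terms = [Term(id=t, name=f"synthetic term {t}", namespace=namespace) for t in ids]
    return OntologyGraph(terms, edges)


def generate_synthetic_corpus(
    graph: OntologyGraph,
    n_genes: int,
    terms_per_gene: tuple[int, int] = (2, 6),
    iea_fraction: float = 0.3,
    depth_bias: float = 1.0,
    seed: int = 0,
    namespace: str | None = None,
) -> GeneAnnotationSet:
    """Annotate synthetic genes to ontology terms, biased towards deep terms.

    Each gene draws a uniform number of distinct terms in ``terms_per_gene``;
    a term is sampled with probability proportional to ``depth ** depth_bias``
    so specific terms dominate, as in real annotation corpora.  A fraction
    ``iea_fraction`` of the records is labelled with the IEA evidence code
    (electronically inferred), the rest IDA.
    """
    if len(graph) == 0:
        raise ValueError("empty ontology")
    lo, hi = terms_per_gene
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid terms_per_gene range {terms_per_gene}")
    if namespace is None:
        namespace = graph.namespaces[0]
    aspect = NAMESPACE_TO_ASPECT[namespace]

    term_ids = graph.term_ids(namespace)
    weights = [float(graph.depth(t)) ** depth_bias if graph.depth(t) > 0 else (1.0 if depth_bias == 0 else 0.0) for t in term_ids]
    if sum(weights) == 0:
        raise ValueError("no terms with positive sampling weight")

    rng = random.Random(seed)
    records: list[AnnotationRecord] = []
    for i in range(n_genes):
        gene = f"GENE{i + 1:04d}"
        k = min(rng.randint(lo, hi), len(term_ids))
        chosen: set[str] = set()
        while len(chosen) < k:
            chosen.add(rng.choices(term_ids, weights=weights, k=1)[0])
        for term in sorted(chosen):
            evidence = "IEA" if rng.random() < iea_fraction else "IDA"
            records.append(AnnotationRecord(gene, term, evidence, aspect))
    return GeneAnnotationSet(records, graph=graph, provenance=f"synthetic|seed={seed}")
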