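"""Gene-gene functional similarity measures.

The headline measure is the weighted-inherited-semantics (WIS) similarity:
annotate each gene with the ancestor closure of its direct GO terms, measure
the IC of the intersection and of the union of the two closures with the
weighted set-IC accumulation, and take their ratio

    Fun_sim(g1, g2) = IC(T_g1 ∩ T_g2) / IC(T_g1 ∪ T_g2).

Every baseline the method is usually compared against is implemented on the
same containers:

* groupwise — simUI (term-set Jaccard), simGIC (IC-weighted Jaccard), the
  unit-weight inheritance variant (full inheritance, no edge weights), and an
  IC-weighted annotation-vector measure;
* pairwise — Resnik / Lin / Jiang-Conrath / simRel on the most informative
  common ancestor (MICA), combined over annotation-term grids by the average,
  maximum or best-match-average (BMA) rule;
* Wang's semantic-value method, with either the classic fixed per-relation
  edge weights (is_a 0.8, part_of 0.6) or the descendant-ratio weights of the
  WIS scheme ("WangWV").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .ontology import Corpus, GeneAnnotationSet, OntologyGraph
from .set_ic import WeightedEdgeTable, set_ic
from .term_ic import ICTable

PAIRWISE_MEASURES = ("resnik", "lin", "jc", "simrel")
COMBINE_RULES = ("avg", "max", "bma")
WANG_FIXED_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def _closure(g: OntologyGraph, ann: GeneAnnotationSet, gene: str) -> frozenset[str]:
    return frozenset(g.ancestor_closure(ann.terms(gene)))


def _ratio(numerator: float, denominator: float, g1: str, g2: str) -> float:
    if denominator <= 0.0:
        warnings.warn(
            f"zero-IC union for genes {g1}/{g2} (annotated only to the root); "
            "similarity defined as 0",
            stacklevel=3,
        )
        return 0.0
    return numerator / denominator


# ---------------------------------------------------------------------------
# Groupwise measures
# ---------------------------------------------------------------------------


def wis_similarity(
    g: OntologyGraph,
    ic: ICTable,
    weights: WeightedEdgeTable,
    ann: GeneAnnotationSet,
    g1: str,
    g2: str,
    floor: bool = True,
) -> float:
    """Set-IC overlap ratio of the two genes' ancestor-closed term sets.

    Symmetric; 1 for identical annotation sets; within [0, 1] when extended-IC
    flooring is on.  A pair whose closures intersect only at the root scores 0.
    """
    t1, t2 = _closure(g, ann, g1), _closure(g, ann, g2)
    union = t1 | t2
    inter = t1 & t2
    denom = set_ic(ic, weights, g, union, floor=floor).total
    if not inter:
        return 0.0
    numer = set_ic(ic, weights, g, inter, floor=floor).total
    return _ratio(numer, denom, g1, g2)


def teng_similarity(
    g: OntologyGraph,
    ic: ICTable,
    weights: WeightedEdgeTable,
    ann: GeneAnnotationSet,
    g1: str,
    g2: str,
    floor: bool = True,
) -> float:
    """Set-IC overlap ratio under full (unit-weight) inheritance."""
    t1, t2 = _closure(g, ann, g1), _closure(g, ann, g2)
    union = t1 | t2
    inter = t1 & t2
    denom = set_ic(ic, weights, g, union, floor=floor, weighting="unit").total
    if not inter:
        return 0.0
    numer = set_ic(ic, weights, g, inter, floor=floor, weighting="unit").total
    return _ratio(numer, denom, g1, g2)


def sim_ui(g: OntologyGraph, ann: GeneAnnotationSet, g1: str, g2: str) -> float:
    """Jaccard index of the two ancestor-closed term sets."""
    t1, t2 = _closure(g, ann, g1), _closure(g, ann, g2)
    return len(t1 & t2) / len(t1 | t2)


def sim_gic(
    g: OntologyGraph, ic: ICTable, ann: GeneAnnotationSet, g1: str, g2: str
) -> float:
    """IC-weighted Jaccard: sum of IC over the intersection / over the union."""
    t1, t2 = _closure(g, ann, g1), _closure(g, ann, g2)
    numer = sum(ic[t] for t in t1 & t2)
    denom = sum(ic[t] for t in t1 | t2)
    return _ratio(numer, denom, g1, g2)


def vector_cosine_similarity(
    g: OntologyGraph,
    ic: ICTable,
    ann: GeneAnnotationSet,
    g1: str,
    g2: str,
    standard_cosine: bool = False,
) -> float:
    """Inner product of IC-weighted annotation-closure vectors.

    The default denominator is ``sqrt(|g1|^2 + |g2|^2)`` — the form this
    family of vector measures is usually written in, although it is not a
    true cosine (identical vectors score ``norm/sqrt(2)``, not 1).
    ``standard_cosine`` switches to the usual ``|g1| * |g2|`` denominator.
    """
    t1, t2 = _closure(g, ann, g1), _closure(g, ann, g2)
    dot = sum(ic[t] * ic[t] for t in t1 & t2)
    sq1 = sum(ic[t] * ic[t] for t in t1)
    sq2 = sum(ic[t] * ic[t] for t in t2)
    if standard_cosine:
        denom = np.sqrt(sq1) * np.sqrt(sq2)
    else:
        denom = np.sqrt(sq1 + sq2)
    return _ratio(dot, float(denom), g1, g2)


# ---------------------------------------------------------------------------
# Pairwise (term-level) measures
# ---------------------------------------------------------------------------


def mica(g: OntologyGraph, ic: ICTable, t1: str, t2: str) -> str:
    """Most informative common ancestor (self-inclusive); ties by term id."""
    if g.namespace_of(t1) != g.namespace_of(t2):
        raise ValueError(f"{t1} and {t2} are in different namespaces")
    common = g.ancestors(t1, include_self=True) & g.ancestors(t2, include_self=True)
    return min(common, key=lambda t: (-ic[t], t))


def term_pair_similarity(
    g: OntologyGraph,
    ic: ICTable,
    t1: str,
    t2: str,
    measure: str,
    corpus: Corpus | None = None,
) -> float:
    """Similarity of two terms under one MICA-based measure.

    resnik: ``IC(MICA)``; lin: ``2 IC(MICA) / (IC(t1) + IC(t2))`` (0 when both
    ICs are 0); jc: ``1 / (1 + IC(t1) + IC(t2) - 2 IC(MICA))`` (distance to
    similarity); simrel: ``lin * (1 - p(MICA))`` with the annotation
    probability from a corpus.
    """
    if measure not in PAIRWISE_MEASURES:
        raise ValueError(f"unknown pairwise measure {measure!r}")
    a = mica(g, ic, t1, t2)
    ic_mica = ic[a]
    if measure == "resnik":
        return ic_mica
    if measure == "jc":
        return 1.0 / (1.0 + ic[t1] + ic[t2] - 2.0 * ic_mica)
    denom = ic[t1] + ic[t2]
    lin = 2.0 * ic_mica / denom if denom > 0 else 0.0
    if measure == "lin":
        return lin
    if corpus is None:
        raise ValueError("simrel requires a corpus for p(MICA)")
    return lin * (1.0 - corpus.probability(g, a))


def combine_pairwise(grid: np.ndarray, rule: str) -> float:
    """Combine a term-pair similarity grid into one gene-level value.

    ``avg`` / ``max`` are as named; ``bma`` averages the row maxima together
    with the column maxima (best-match average), which is symmetric in the two
    term lists.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty similarity grid")
    if rule == "avg":
        return float(grid.mean())
    if rule == "max":
        return float(grid.max())
    if rule == "bma":
        best = np.concatenate([grid.max(axis=1), grid.max(axis=0)])
        return float(best.mean())
    raise ValueError(f"unknown combination rule {rule!r}")


def pairwise_gene_similarity(
    g: OntologyGraph,
    ic: ICTable,
    ann: GeneAnnotationSet,
    g1: str,
    g2: str,
    measure: str = "resnik",
    combine: str = "bma",
    corpus: Corpus | None = None,
) -> float:
    """Term-pair grid over the genes' direct annotations, then combine."""
    terms1 = sorted(ann.terms(g1))
    terms2 = sorted(ann.terms(g2))
    grid = np.array(
        [
            [term_pair_similarity(g, ic, a, b, measure, corpus) for b in terms2]
            for a in terms1
        ]
    )
    return combine_pairwise(grid, combine)


# ---------------------------------------------------------------------------
# Wang semantic-value measure
# ---------------------------------------------------------------------------


def _wang_svalues(
    g: OntologyGraph,
    term: str,
    weight_scheme: str,
    weights: WeightedEdgeTable | None,
) -> dict[str, float]:
    """S-values of all ancestors of ``term`` (semantic contributions to it)."""
    closure = g.ancestor_closure({term})
    order = [t for t in g.topological_order() if t in closure]
    s: dict[str, float] = {term: 1.0}
    for t in reversed(order):  # children before parents
        if t == term:
            continue
        best = 0.0
        for child in g.children(t):
            if child not in s:
                continue
            if weight_scheme == "fixed":
                w = WANG_FIXED_WEIGHTS[g.relation(child, t)]
            else:
                assert weights is not None
                w = weights[(child, t)]
            best = max(best, w * s[child])
        s[t] = best
    return s


def wang_term_similarity(
    g: OntologyGraph,
    t1: str,
    t2: str,
    weight_scheme: str = "fixed",
    weights: WeightedEdgeTable | None = None,
) -> float:
    """Wang's S-value term similarity under a chosen edge-weight scheme."""
    if weight_scheme not in ("fixed", "eq11"):
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    if weight_scheme == "eq11" and weights is None:
        raise ValueError("eq11 weighting requires a WeightedEdgeTable")
    s1 = _wang_svalues(g, t1, weight_scheme, weights)
    s2 = _wang_svalues(g, t2, weight_scheme, weights)
    shared = set(s1) & set(s2)
    return sum(s1[t] + s2[t] for t in shared) / (sum(s1.values()) + sum(s2.values()))


def wang_similarity(
    g: OntologyGraph,
    ann: GeneAnnotationSet,
    g1: str,
    g2: str,
    weight_scheme: str = "fixed",
    weights: WeightedEdgeTable | None = None,
    combine: str = "bma",
) -> float:
    """Gene-level Wang similarity (term grid combined by BMA by default)."""
    terms1 = sorted(ann.terms(g1))
    terms2 = sorted(ann.terms(g2))
    grid = np.array(
        [
            [wang_term_similarity(g, a, b, weight_scheme, weights) for b in terms2]
            for a in terms1
        ]
    )
    return combine_pairwise(grid, combine)


# ---------------------------------------------------------------------------
# Measure registry and similarity matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasureSpec:
    """Declarative description of one gene-similarity measure.

    ``name`` is one of: wis, teng, simui, simgic, cosine, wang, wangwv,
    resnik, lin, jc, simrel.  Pairwise names accept a ``combine`` rule.
    """

    name: str = "wis"
    combine: str = "bma"
    floor: bool = True
    standard_cosine: bool = False

    def describe(self) -> str:
        bits = [self.name]
        if self.name in PAIRWISE_MEASURES + ("wang", "wangwv"):
            bits.append(self.combine)
        if self.name == "wis":
            bits.append("floor" if self.floor else "no-floor")
        return "-".join(bits)


def make_measure(
    spec: MeasureSpec,
    g: OntologyGraph,
    ic: ICTable | None = None,
    weights: WeightedEdgeTable | None = None,
    corpus: Corpus | None = None,
) -> Callable[[GeneAnnotationSet, str, str], float]:
    """Bind a measure spec to ontology/IC/weight tables; returns a pair scorer."""
    name = spec.name.lower()

    def need(obj, what: str):
        if obj is None:
            raise ValueError(f"measure {name!r} requires {what}")
        return obj

    if name == "wis":
        ic_, w_ = need(ic, "an ICTable"), need(weights, "a WeightedEdgeTable")
        return lambda ann, a, b: wis_similarity(g, ic_, w_, ann, a, b, floor=spec.floor)
    if name == "teng":
        ic_, w_ = need(ic, "an ICTable"), need(weights, "a WeightedEdgeTable")
        return lambda ann, a, b: teng_similarity(g, ic_, w_, ann, a, b, floor=spec.floor)
    if name == "simui":
        return lambda ann, a, b: sim_ui(g, ann, a, b)
    if name == "simgic":
        ic_ = need(ic, "an ICTable")
        return lambda ann, a, b: sim_gic(g, ic_, ann, a, b)
    if name == "cosine":
        ic_ = need(ic, "an ICTable")
        return lambda ann, a, b: vector_cosine_similarity(
            g, ic_, ann, a, b, standard_cosine=spec.standard_cosine
        )
    if name == "wang":
        return lambda ann, a, b: wang_similarity(
            g, ann, a, b, weight_scheme="fixed", combine=spec.combine
        )
    if name == "wangwv":
        w_ = need(weights, "a WeightedEdgeTable")
        return lambda ann, a, b: wang_similarity(
            g, ann, a, b, weight_scheme="eq11", weights=w_, combine=spec.combine
        )
    if name in PAIRWISE_MEASURES:
        ic_ = need(ic, "an ICTable")
        if name == "simrel":
            need(corpus, "a Corpus")
        return lambda ann, a, b: pairwise_gene_similarity(
            g, ic_, ann, a, b, measure=name, combine=spec.combine, corpus=corpus
        )
    raise ValueError(f"unknown measure {spec.name!r}")


@dataclass
class SimilarityMatrix:
    """Symmetric gene x gene similarity values for one measure."""

    genes: list[str]
    values: np.ndarray
    measure: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match gene list")

    def get(self, g1: str, g2: str) -> float:
        i, j = self.genes.index(g1), self.genes.index(g2)
        return float(self.values[i, j])

    def write_tsv(self, path: str | Path, long_format: bool = False) -> None:
        lines = [f"# measure={self.measure}"]
        if long_format:
            lines.append("gene1\tgene2\tscore")
            for i, a in enumerate(self.genes):
                for j, b in enumerate(self.genes):
                    if j > i:
                        lines.append(f"{a}\t{b}\t{self.values[i, j]:.12g}")
        else:
            lines.append("\t".join(["gene"] + self.genes))
            for i, a in enumerate(self.genes):
                row = "\t".join(f"{v:.12g}" for v in self.values[i])
                lines.append(f"{a}\t{row}")
        Path(path).write_text("\n".join(lines) + "\n")


def similarity_matrix(
    pair_fn: Callable[[GeneAnnotationSet, str, str], float],
    ann: GeneAnnotationSet,
    genes: Sequence[str] | None = None,
    measure: str = "",
) -> SimilarityMatrix:
    """Score all gene pairs once (upper triangle) and mirror."""
    gene_list = sorted(genes) if genes is not None else ann.genes
    for gene in gene_list:
        if gene not in ann:
            raise KeyError(f"gene {gene} has no annotations")
    n = len(gene_list)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = pair_fn(ann, gene_list[i], gene_list[j])
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(gene_list, values, measure=measure)
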