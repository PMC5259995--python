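"""Information-content models for ontology terms.

The information content (IC) of a term quantifies how specific it is.  Five
models are provided:

* ``corpus`` — classic annotation-frequency IC, ``-log p(t)`` where ``p(t)``
  is the probability that a term or one of its descendants annotates a gene
  in a corpus.
* ``seco`` — structural IC from descendant counts,
  ``1 - log(des(t)) / log(total_terms)`` (root 0, leaves 1).
* ``teng`` — depth times the Seco factor, so IC grows with both specificity
  and placement depth.
* ``sanchez`` — ``-log((|leaves(t)|/|AS(t)| + 1) / (max_leaves + 1))``,
  combining leaf coverage with ancestor counts.
* ``wis`` — weighted-inherited-semantics IC,
  ``depth(t) * log(|AS(t)|) * (1 - log(sum_{a in DS(t)} 1/depth(a) + 1) / log(max_nodes))``,
  which uses the depth, the ancestor count and the topology of the
  descendants; it increases strictly along every edge of the DAG.

Here ``AS(t)`` is the ancestor set of ``t`` including ``t`` itself, ``DS(t)``
the descendant set including ``t``, and ``max_nodes`` the term count of the
namespace.  The root of each namespace has IC 0 under every structural model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .ontology import Corpus, OntologyGraph

MODELS = ("corpus", "seco", "teng", "sanchez", "wis")


@dataclass(frozen=True)
class ICModelConfig:
    """Configuration of one IC model run.

    ``log_base`` rescales every logarithm; it cancels in IC-ratio similarity
    scores and only matters for reporting.  ``seco_printed_variant`` switches
    the Seco-style factor to the alternative form
    ``1 - (log(des)+1)/log(total)``, which goes negative near the root and is
    kept for fidelity studies only.
    """

    model: str = "wis"
    normalize: bool = False
    log_base: float = math.e
    seco_printed_variant: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown IC model {self.model!r}")
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")


@dataclass
class ICTable:
    """Per-term IC values for one model configuration."""

    values: dict[str, float]
    config: ICModelConfig
    flagged: set[str] = field(default_factory=set)  # zero-count corpus terms

    def __getitem__(self, term_id: str) -> float:
        return self.values[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.values

    def __len__(self) -> int:
        return len(self.values)

    def max_value(self) -> float:
        return max(self.values.values())

    def normalized(self) -> "ICTable":
        """Divide by the maximum value; idempotent, for distribution plots."""
        top = self.max_value()
        if top <= 0:
            raise ValueError("cannot normalize an all-zero IC table")
        vals = {t: v / top for t, v in self.values.items()}
        return ICTable(vals, replace(self.config, normalize=True), set(self.flagged))

    def scaled(self, factor: float) -> "ICTable":
        return ICTable(
            {t: v * factor for t, v in self.values.items()},
            self.config,
            set(self.flagged),
        )

    def write_tsv(self, path: str | Path) -> None:
        lines = [f"# model={self.config.model} normalize={self.config.normalize} log_base={self.config.log_base:g}"]
        lines += [f"{t}\t{v:.12g}" for t, v in sorted(self.values.items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, config: ICModelConfig | None = None) -> "ICTable":
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            term, val = line.split("\t")
            values[term] = float(val)
        return cls(values, config or ICModelConfig(model="wis"))


def _log(x: float, base: float) -> float:
    return math.log(x) / math.log(base)


def _seco_factor(g: OntologyGraph, t: str, config: ICModelConfig) -> float:
    des = g.descendant_count(t)  # includes t itself
    total = g.max_nodes(g.namespace_of(t))
    if total < 2:
        raise ValueError("namespace too small for a structural IC model")
    if config.seco_printed_variant:
        return 1.0 - (_log(des, config.log_base) + 1.0) / _log(total, config.log_base)
    return 1.0 - _log(des, config.log_base) / _log(total, config.log_base)


def ic_corpus(
    g: OntologyGraph,
    corpus: Corpus,
    t: str,
    config: ICModelConfig | None = None,
) -> float:
    """Annotation-frequency IC, ``-log p(t)``.

    A term with zero propagated count has undefined (infinite) IC; it is
    assigned the maximum IC observed over annotated terms of its namespace so
    downstream ratios stay finite (such terms are flagged in ``ic_table``).
    """
    config = config or ICModelConfig(model="corpus")
    ns = g.namespace_of(t)
    if corpus.propagated.get(t, 0) > 0:
        return -_log(corpus.probability(g, t), config.log_base)
    finite = [
        -_log(corpus.probability(g, u), config.log_base)
        for u in g.term_ids(ns)
        if corpus.propagated.get(u, 0) > 0
    ]
    if not finite:
        raise ValueError(f"corpus has no annotated terms in namespace {ns}")
    return max(finite)


def ic_seco(g: OntologyGraph, t: str, config: ICModelConfig | None = None) -> float:
    """Descendant-count IC: 0 at the root, 1 at every leaf."""
    config = config or ICModelConfig(model="seco")
    return _seco_factor(g, t, config)


def ic_teng(g: OntologyGraph, t: str, config: ICModelConfig | None = None) -> float:
    """Depth-weighted descendant-count IC: ``depth(t) * seco(t)``."""
    config = config or ICModelConfig(model="teng")
    return g.depth(t) * _seco_factor(g, t, config)


def ic_sanchez(g: OntologyGraph, t: str, config: ICModelConfig | None = None) -> float:
    """Leaf/ancestor IC; leaves score ``log(max_leaves + 1)``, the root 0.

    ``leaves(t)`` counts leaf descendants of ``t`` (empty when ``t`` is a
    leaf); ``AS(t)`` includes ``t`` itself.
    """
    config = config or ICModelConfig(model="sanchez")
    ns = g.namespace_of(t)
    n_leaves = g.leaf_descendant_count(t)
    n_anc = len(g.ancestors(t, include_self=True))
    max_leaves = len(g.leaves(ns))
    return -_log((n_leaves / n_anc + 1.0) / (max_leaves + 1.0), config.log_base)


def ic_wis(g: OntologyGraph, t: str, config: ICModelConfig | None = None) -> float:
    """Weighted-inherited-semantics IC.

    ``depth(t) * log(|AS(t)|) * (1 - log(S + 1)/log(max_nodes))`` with
    ``S = sum over descendants a of t (including t) of 1/depth(a)``.  The root
    has IC 0 by convention (its depth factor is 0 regardless), so the
    undefined ``1/depth(root)`` term never arises: no non-root term has the
    root among its descendants.
    """
    config = config or ICModelConfig(model="wis")
    ns = g.namespace_of(t)
    if g.root_of(t) == t:
        return 0.0
    depth = g.depth(t)
    n_anc = len(g.ancestors(t, include_self=True))
    inv_depth_sum = sum(1.0 / g.depth(a) for a in g.descendants(t, include_self=True))
    max_nodes = g.max_nodes(ns)
    if max_nodes < 2:
        raise ValueError("namespace too small for the WIS IC model")
    factor = 1.0 - _log(inv_depth_sum + 1.0, config.log_base) / _log(max_nodes, config.log_base)
    return depth * _log(n_anc, config.log_base) * factor


_PER_TERM = {
    "seco": ic_seco,
    "teng": ic_teng,
    "sanchez": ic_sanchez,
    "wis": ic_wis,
}


def ic_table(
    g: OntologyGraph,
    config: ICModelConfig,
    corpus: Corpus | None = None,
    namespace: str | None = None,
) -> ICTable:
    """Compute IC for every term of a namespace (or the whole graph)."""
    term_ids = g.term_ids(namespace)
    flagged: set[str] = set()
    values: dict[str, float] = {}
    if config.model == "corpus":
        if corpus is None:
            raise ValueError("the corpus IC model requires a Corpus")
        for t in term_ids:
            values[t] = ic_corpus(g, corpus, t, config)
            if corpus.propagated.get(t, 0) == 0:
                flagged.add(t)
    else:
        fn = _PER_TERM[config.model]
        for t in term_ids:
            values[t] = fn(g, t, config)
    table = ICTable(values, config, flagged)
    if config.normalize:
        table = table.normalized()
    return table


@dataclass
class ICDistribution:
    """Histogram of normalized IC values plus the cumulative curve."""

    bin_edges: np.ndarray
    masses: np.ndarray
    cumulative: np.ndarray

    def top_decile_mass(self) -> float:
        """Fraction of terms whose normalized IC falls in the top ten percent."""
        n_top = max(1, round(0.1 * (len(self.bin_edges) - 1)))
        return float(self.masses[-n_top:].sum())

    def write_tsv(self, path: str | Path) -> None:
        lines = ["lower\tupper\tmass\tcumulative"]
        for i, m in enumerate(self.masses):
            lines.append(
                f"{self.bin_edges[i]:.6g}\t{self.bin_edges[i + 1]:.6g}"
                f"\t{m:.12g}\t{self.cumulative[i]:.12g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def ic_distribution(table: ICTable, n_bins: int = 20) -> ICDistribution:
    """Bin a (normalized) IC table into masses summing to 1.

    The table is max-normalized first if it is not already, so the histogram
    always spans [0, 1].
    """
    if len(table) == 0:
        raise ValueError("empty IC table")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vals = np.array(list(table.values.values()), dtype=float)
    top = vals.max()
    if top > 0:
        vals = vals / top
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    masses = counts / counts.sum()
    return ICDistribution(edges, masses, np.cumsum(masses))
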