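"""Evaluation machinery for gene-similarity matrices.

Four tools mirror how functional-similarity measures are usually benchmarked:

* ROC / AUC over a labelled set of gene pairs (e.g. interacting vs random
  pairs), sweeping a similarity threshold over (0, 1);
* F1-score versus classification cutoff, with the mean and maximum F1 as
  scalar summaries;
* Pearson correlation between similarity values and an external reference
  (e.g. co-expression);
* complete-linkage hierarchical clustering of a similarity matrix, with
  cut-at-k cluster extraction and Newick export of the dendrogram.

Distances for clustering are ``1 - similarity``.  Genes are canonically
sorted before clustering so the result is invariant under input permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .gene_similarity import SimilarityMatrix
from .ontology import GeneAnnotationSet


@dataclass
class LabelledPairs:
    """Gene pairs labelled positive (1) or negative (0)."""

    pairs: list[tuple[str, str, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for g1, g2, label in self.pairs:
            key = frozenset((g1, g2))
            if key in seen:
                raise ValueError(f"duplicate pair ({g1}, {g2})")
            seen.add(key)
            if label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {label!r}")

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=int)

    def scores_from(self, matrix: SimilarityMatrix) -> np.ndarray:
        return np.array([matrix.get(g1, g2) for g1, g2, _ in self.pairs])

    def write_tsv(self, path: str | Path) -> None:
        lines = [
            f"{g1}\t{g2}\t{'positive' if lab else 'negative'}"
            for g1, g2, lab in self.pairs
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LabelledPairs":
        pairs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            g1, g2, lab = line.split("\t")
            pairs.append((g1, g2, 1 if lab.strip().lower() == "positive" else 0))
        return cls(pairs, provenance=str(path))


def sample_negative_pairs(
    ann: GeneAnnotationSet,
    positives: Iterable[tuple[str, str]],
    seed: int = 0,
) -> LabelledPairs:
    """Class-balanced labelled pairs: the positives plus an equal number of
    random annotated gene pairs absent from the positive set."""
    import random

    pos = [tuple(p) for p in positives]
    pos_keys = {frozenset(p) for p in pos}
    genes = ann.genes
    rng = random.Random(seed)
    negatives: list[tuple[str, str]] = []
    neg_keys: set[frozenset] = set()
    max_tries = 1000 * max(1, len(pos))
    tries = 0
    while len(negatives) < len(pos):
        tries += 1
        if tries > max_tries:
            raise ValueError("could not sample enough distinct negative pairs")
        g1, g2 = rng.sample(genes, 2)
        key = frozenset((g1, g2))
        if key in pos_keys or key in neg_keys:
            continue
        neg_keys.add(key)
        negatives.append((g1, g2))
    pairs = [(g1, g2, 1) for g1, g2 in pos] + [(g1, g2, 0) for g1, g2 in negatives]
    return LabelledPairs(pairs, provenance=f"sampled negatives, seed={seed}")


# ---------------------------------------------------------------------------
# ROC / F1 / Pearson
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def write_tsv(self, path: str | Path) -> None:
        lines = ["threshold\tfpr\ttpr"]
        for t, f, s in zip(self.thresholds, self.fpr, self.tpr):
            lines.append(f"{t:.12g}\t{f:.12g}\t{s:.12g}")
        Path(path).write_text("\n".join(lines) + "\n")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve and area by sweeping thresholds over the observed scores.

    Tied scores enter the curve together, so the trapezoid-rule area equals
    the Mann-Whitney U statistic with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both positive and negative labels")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return ROCResult(thr, fpr, tpr, float(_sk_auc(fpr, tpr)))


@dataclass
class F1Curve:
    cutoffs: np.ndarray
    f1: np.ndarray
    mean_f1: float
    max_f1: float
    argmax_cutoff: float

    def write_tsv(self, path: str | Path) -> None:
        lines = ["cutoff\tf1"]
        for c, f in zip(self.cutoffs, self.f1):
            lines.append(f"{c:.12g}\t{f:.12g}")
        Path(path).write_text("\n".join(lines) + "\n")


def f1_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    cutoffs: Sequence[float] | None = None,
) -> F1Curve:
    """F1 (harmonic mean of precision and recall) at each cutoff.

    A pair is predicted positive when its score is strictly greater than the
    cutoff.  F1 is 0 where precision or recall is undefined.  The default
    grid is 101 evenly spaced cutoffs in [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    grid = np.linspace(0.0, 1.0, 101) if cutoffs is None else np.asarray(cutoffs, float)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    f1s = np.zeros_like(grid)
    for i, c in enumerate(grid):
        pred = scores > c
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        if tp == 0:
            f1s[i] = 0.0
        else:
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
            f1s[i] = 2 * precision * recall / (precision + recall)
    best = int(np.argmax(f1s))
    return F1Curve(grid, f1s, float(f1s.mean()), float(f1s.max()), float(grid[best]))


def pearson(similarities: Sequence[float], reference: Sequence[float]) -> float:
    """Product-moment correlation between similarity and a reference signal."""
    x = np.asarray(similarities, dtype=float)
    y = np.asarray(reference, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Complete-linkage clustering
# ---------------------------------------------------------------------------


@dataclass
class LinkageTree:
    """Complete-linkage dendrogram over genes (distance = 1 - similarity)."""

    genes: list[str]
    linkage: np.ndarray  # scipy linkage matrix over the sorted gene list

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Assign each gene to one of ``k`` clusters (labels 1..k)."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.genes, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.genes)
        buf = StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def complete_linkage(matrix: SimilarityMatrix) -> LinkageTree:
    """Complete-linkage hierarchical clustering of a similarity matrix.

    Genes are sorted lexicographically first, so the tree does not depend on
    the input ordering.  Requires a symmetric matrix; the diagonal is ignored
    (treated as distance 0).
    """
    values = np.asarray(matrix.values, dtype=float)
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    order = np.argsort(matrix.genes)
    genes = [matrix.genes[i] for i in order]
    sims = values[np.ix_(order, order)]
    dist = 1.0 - sims
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="complete")
    return LinkageTree(genes, linkage)


def evaluation_summary(
    scores: Sequence[float], labels: Sequence[int]
) -> dict[str, float]:
    """AUC plus F1-curve summaries as one JSON-ready dict."""
    roc = roc_auc(scores, labels)
    f1 = f1_curve(scores, labels)
    return {
        "auc": roc.auc,
        "mean_f1": f1.mean_f1,
        "max_f1": f1.max_f1,
        "argmax_cutoff": f1.argmax_cutoff,
    }


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
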