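# Methods

## Ontology model

Each GO namespace (biological_process, molecular_function,
cellular_component) is an independent rooted DAG with child→parent edges of
type `is_a` or `part_of` (configurable; other relation types are out of
scope). Obsolete terms are dropped at load time; `alt_id`s map to primary
ids; annotations to unknown terms are discarded with a logged count.
NOT-qualified GAF records are always excluded, which is standard practice.

**Depth** is the length of the *longest* path from the namespace root
(`depth(root) = 0`). The longest-path convention honours a term's most
specific placement and guarantees `depth(child) ≥ depth(parent) + 1` on every
edge, which in turn underpins the strict monotonicity of the WIS IC model.
All orderings (topological order, matrix gene order, tie-breaks) are
lexicographic on identifiers, so every computation is deterministic.

## Term IC models

Let `des(t)` and `Dst(t)` count descendants including `t` itself, `AS(t)` be
the self-inclusive ancestor set, and `total_terms`/`max_nodes`/`max_leaves`
be namespace totals. Natural logarithms are used throughout; the base is
configurable but cancels in every similarity ratio.

| model | formula | root | leaf |
|---|---|---|---|
| corpus | `−log(propagated(t)/propagated(root))` | 0 | data-dependent |
| seco | `1 − log(des(t))/log(total_terms)` | 0 | 1 |
| teng | `depth(t) × seco(t)` | 0 | `depth` |
| sanchez | `−log((leaves(t)/|AS(t)| + 1)/(max_leaves + 1))` | ≈0 | `log(max_leaves+1)` |
| wis | `depth(t)·log|AS(t)|·(1 − log(Σ_{a∈DS(t)} 1/depth(a) + 1)/log(max_nodes))` | 0 | grows with depth |

Numerical choices:

* An alternative Seco-style form with the `+1` inside the numerator,
  `1 − (log(des)+1)/log(total)`, is negative at the root; the canonical form
  above is the default and the other is available behind
  `seco_printed_variant` for fidelity studies.
* `AS(t)` includes `t` itself in the sanchez and wis formulas; otherwise
  `log|AS| = log 1 = 0` would zero the IC of every depth-1 single-parent
  term and break monotonicity.
* The root's WIS IC is defined as 0 directly (its depth factor is 0 anyway),
  so the undefined `1/depth(root)` term never arises — no non-root term has
  the root among its descendants.
* Corpus IC of a zero-count term is set to the maximum IC observed over
  annotated terms of its namespace (and flagged) instead of infinity, so
  simGIC and simRel stay finite.
* Raw WIS ICs exceed 1. Max-normalization to [0,1] is applied only for
  distribution reporting; similarity scores are ratios and are invariant
  under any global positive rescaling of the IC table (tested to 1e-12).

Corpus counts propagate by summing each directly annotated term's
de-duplicated (gene, term) count into all of its ancestors, so the root's
propagated count equals the total pair count of its namespace.

## Edge weights and set IC

The inheritance weight of an edge is `ω = Dst(child)/Dst(parent)` with
descendant counts taken on the **whole namespace graph**, never a displayed
sub-graph. Self-inclusive counting makes ω strictly positive on leaf edges
and strictly below 1 everywhere.

The IC of a term set is accumulated as follows: ancestor-close the set (the
closure is logged if terms had to be added — a parent outside the set would
otherwise contribute nothing, and closure makes that case unreachable),
iterate in topological order, and add each term's extended IC
`IC(t) − Σ_{p present} ω_{t→p} IC(p)`. The result is order-invariant: the
total equals the closed form `Σ_{t∈S} IC(t) − Σ_{(t→p)⊆S} ω·IC(p)`, which is
also implemented independently (`set_ic_oracle`) and cross-checked to 1e-12.

With several high-ω parents the extended IC can go negative. **Flooring at
0 is the default**: it leaves any all-positive accumulation unchanged, makes
set IC monotone under set inclusion, and therefore bounds the similarity
ratio in [0, 1]. `floor=False` preserves the literal arithmetic and is used
in the oracle-equivalence tests. Unit weighting (`weighting="unit"`)
recovers full inheritance: on a chain the contributions telescope to the
deepest term's IC.

## Similarity measures

Gene term sets are ancestor-closed before every groupwise measure and
de-duplicated. Pairwise measures operate on the direct annotation sets and
are combined by avg, max or BMA (mean of row maxima and column maxima; BMA
always lies between avg and max). Genes annotated only to the root would
produce a 0/0 ratio; they score 0 against everything except themselves, with
a warning.

* The annotation-vector measure defaults to the denominator
  `√(|g1|² + |g2|²)`, the form this family is usually written in even though
  it is not a true cosine (identical vectors score `‖g‖/√2`);
  `standard_cosine=True` gives the conventional `‖g1‖·‖g2‖` denominator.
* Jiang–Conrath distance is mapped to similarity as `1/(1 + distance)`.
* simRel multiplies Lin by `1 − p(MICA)`; its self-similarity is below 1 by
  design (it penalises uninformative shared annotations).
* Wang's method supports the classic fixed per-relation weights (is_a 0.8,
  part_of 0.6) and the descendant-ratio weights of the WIS scheme
  ("WangWV").
* Pairwise measures default to the WIS IC table for structural IC and a
  corpus table for `p(MICA)`; both are injectable, since different IC
  sources are legitimately in use.

## Evaluation

ROC curves sweep thresholds over the observed scores with tied scores
entering together, so the trapezoid AUC equals the Mann–Whitney U statistic
with ties counted half (asserted against a brute-force pair counter). F1
curves predict positive for score strictly greater than the cutoff, on a
default grid of 101 evenly spaced cutoffs in [0, 1]; mean and max F1 plus
the argmax cutoff are reported. Negative benchmark pairs are sampled
class-balanced from annotated gene pairs absent from the positive set,
seeded. Clustering uses complete linkage on distance `1 − similarity`; genes
are sorted lexicographically first so the dendrogram is invariant under
input permutation, and the tree exports to Newick (branch lengths from merge
heights) and supports cut-at-k extraction.

## Synthetic data

The generator emulates the gross structure of a GO namespace: a single root,
layered terms (each non-root term draws 1–`max_parents` parents from
strictly shallower layers, so graphs are acyclic by construction, with one
parent anchored to the deepest populated shallower layer so depth equals the
assigned layer), an `is_a`/`part_of` mix (default 20% part_of, roughly the
GO proportion), and annotation sampling biased toward deep terms
(probability ∝ `depth^bias`, default bias 1), with a configurable IEA
fraction (default 0.3) mirroring the electronically-inferred share real
corpora carry. Defaults of 2–6 direct annotations per gene match typically
sparse GOA entries.

What it does not emulate: the real GO's degree distribution and term-count
imbalance between namespaces, annotation biases toward well-studied genes,
co-annotation correlations, and cross-namespace structure. Passing tests
therefore establish the algorithmic contracts (monotonicity, bounds,
symmetry, oracle equivalence) — not benchmark performance on real GO/GOA
releases, which require the archived datasets.

Problem sizes used in the test suite — DAGs of 120–1000 terms, corpora of
20–50 genes, 100 seeded replicates for oracle equivalence and 10 for
monotonicity sweeps — were chosen as the smallest scales at which every
contract is exercised on non-trivial topology.

## Known limitations

* Strict WIS monotonicity degenerates on a two-term ontology (the root's
  only child has IC 0 because `des`-sum + 1 equals `max_nodes`); any larger
  namespace is unaffected.
* Disjoint-common-ancestor averaging (GraSM) and external benchmark metrics
  (ECC/Pfam/sequence-similarity correlations) are out of scope.
* Relations other than `is_a`/`part_of` (e.g. `regulates`) are not loaded.
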