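# wissim

Gene functional similarity from Gene Ontology annotations, built around the
**weighted inherited semantics (WIS)** family of measures, with the standard
baselines and the evaluation machinery used to benchmark them.

## The problem

Two genes are functionally similar when the GO terms that annotate them carry
similar information. Turning that intuition into a number requires three
ingredients, and each is a modelling choice:

1. **Term specificity (information content, IC).** Besides the classic
   corpus IC, `IC(t) = −log p(t)`, this package implements the structural
   models of Seco (descendant counts), Teng (depth × descendant counts),
   Sanchez (leaves and ancestors) and the WIS model

   ```
   IC(t) = depth(t) · log|AS(t)| · (1 − log(Σ_{a∈DS(t)} 1/depth(a) + 1) / log(max_nodes))
   ```

   where `AS(t)`/`DS(t)` are the ancestor/descendant sets of `t` (both
   self-inclusive), `depth` is the longest root→term path and `max_nodes`
   the namespace term count. WIS IC increases strictly along every edge of
   the DAG.

2. **IC of a term set.** Summing term ICs double-counts semantics shared
   between a term and its parents. Each edge `(t, t_p)` gets an inheritance
   weight `ω = Dst(t)/Dst(t_p)` (descendant counts in the whole namespace, so
   `0 < ω < 1`), and terms are added in topological order, each contributing
   only its *extended* IC: `IC(t) − Σ_p ω_{t→p} · IC(p)` over parents already
   in the set.

3. **Gene similarity.** With `T_g` the ancestor closure of gene `g`'s
   annotations,

   ```
   Fun_sim(g1, g2) = IC(T_g1 ∩ T_g2) / IC(T_g1 ∪ T_g2) ∈ [0, 1].
   ```

Baselines on the same containers: simUI, simGIC, an IC-weighted annotation
vector measure, unit-weight (full) inheritance, Wang's semantic values (fixed
or descendant-ratio edge weights), and pairwise Resnik/Lin/Jiang-Conrath/
simRel with avg/max/best-match-average combination. Evaluation tools cover
ROC/AUC, F1-vs-cutoff curves, Pearson correlation against external references
and complete-linkage hierarchical clustering with Newick export.

A seeded synthetic ontology/annotation generator (valid OBO + GAF output)
lets the entire pipeline run and be tested without downloading GO releases.

## Worked example

`examples/02_set_ic_worked_example.py` runs the set-IC accumulation on a
seven-term DAG with known edge weights:

```
 term        IC  extended IC  running total
   t1    0.0000       0.0000         0.0000
   t2    0.0030       0.0030         0.0030
   t3    0.0110       0.0110         0.0140
   t4    0.0117       0.0100         0.0240
   t5    0.0197       0.0120         0.0360
   t6    0.0304       0.0120         0.0480
   t7    0.0441       0.0030         0.0510

IC of the full set: 0.051
```

Each term contributes its IC minus what it inherits (weighted per edge) from
parents already in the set; the total, 0.051, is well below the naive IC sum
(0.120) because shared semantics are counted once. The other example scripts
compare IC models (`01`), score gene pairs under seven measures (`03`) and
run a PPI-style ROC/F1 benchmark plus clustering (`04`).

## Command line

A thin CLI wraps the library:

```bash
wissim synth --n-terms 500 --n-genes 50 --seed 1 --out fixtures/
wissim ic   --obo fixtures/ontology.obo --ic-model wis --ic-model seco --out ic/
wissim sim  --obo fixtures/ontology.obo --gaf fixtures/annotations.gaf \
            --measure wis --out sim/
wissim eval --matrix sim/matrix.tsv --labels pairs.tsv --clusters 3 --out eval/
```

Every run writes a `config.json` snapshot next to its outputs.

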