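"""Score gene pairs with WIS and the baseline similarity measures.

Generates a synthetic ontology and annotation corpus, then compares a few
gene pairs under the set-IC ratio (wis), its unit-weight variant (teng),
term-set Jaccard (simui), IC-weighted Jaccard (simgic), Wang's method and
Resnik/Lin with best-match-average combination.
"""

from wissim import (
    ICModelConfig,
    MeasureSpec,
    build_corpus,
    compute_edge_weights,
    generate_synthetic_corpus,
    generate_synthetic_ontology,
    ic_table,
    make_measure,
)

g = generate_synthetic_ontology(300, max_depth=7, max_parents=3, seed=3)
ann = generate_synthetic_corpus(g, n_genes=20, terms_per_gene=(2, 4), seed=3)
ics = ic_table(g, ICModelConfig(model="wis"))
weights = compute_edge_weights(g)
corpus = build_corpus(g, ann)

measures = ["wis", "teng", "simui", "simgic", "wang", "resnik", "lin"]
fns = {
    name: make_measure(MeasureSpec(name=name), g, ic=ics, weights=weights,
                       corpus=corpus)
    for name in measures
}

genes = ann.genes
pairs = [(genes[0], genes[1]), (genes[0], genes[5]), (genes[2], genes[2])]
header = f"{'pair':>20}" + "".join(f"{m:>9}" for m in measures)
print(header)
for a, b in pairs:
    row = f"{a + '/' + b:>20}"
    for m in measures:
        row += f"{fns[m](ann, a, b):9.3f}"
    print(row)
print()
print("values near 1 mean the genes' annotation sets carry almost the same")
print("information; resnik is an unnormalized IC and can exceed 1.")
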