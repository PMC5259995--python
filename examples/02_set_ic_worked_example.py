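"""Weighted set-IC accumulation on a seven-term hand example.

A small DAG (t1 root ... t7 most specific) with known edge inheritance
weights.  Terms are added in topological order; each contributes its IC minus
what it inherits, weighted per edge, from parents already in the set.  The
running total is the IC of the term set without double-counting shared
semantics.
"""

from wissim import OntologyGraph, Term, WeightedEdgeTable, set_ic

edges = [("t2", "t1"), ("t3", "t1"), ("t4", "t2"), ("t6", "t4"),
         ("t6", "t3"), ("t5", "t3"), ("t7", "t6"), ("t7", "t5")]
weights = WeightedEdgeTable({
    ("t2", "t1"): 0.80, ("t3", "t1"): 0.46, ("t4", "t2"): 0.57,
    ("t6", "t4"): 0.71, ("t6", "t3"): 0.92, ("t5", "t3"): 0.70,
    ("t7", "t6"): 0.73, ("t7", "t5"): 0.96,
})
term_ic = {"t1": 0.0, "t2": 0.003, "t3": 0.011, "t4": 0.01171,
           "t5": 0.0197, "t6": 0.0304341, "t7": 0.04412889}

graph = OntologyGraph([Term(id=t) for t in term_ic],
                      [(c, p, "is_a") for c, p in edges])
result = set_ic(term_ic, weights, graph, set(term_ic))

running = 0.0
print(f"{'term':>5} {'IC':>9} {'extended IC':>12} {'running total':>14}")
for t in result.terms:
    running += result.contributions[t]
    print(f"{t:>5} {term_ic[t]:9.4f} {result.contributions[t]:12.4f} {running:14.4f}")
print()
print(f"IC of the full set: {result.total:.3f}")
print("each term adds only what it does not inherit from parents in the set;")
print("summing raw ICs instead would give "
      f"{sum(term_ic.values()):.3f} by double-counting shared semantics.")
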