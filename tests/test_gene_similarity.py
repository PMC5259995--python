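"""Gene similarity measures: hand values, contracts, cross-checks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wissim import (
    GeneAnnotationSet,
    ICModelConfig,
    MeasureSpec,
    build_corpus,
    combine_pairwise,
    compute_edge_weights,
    generate_synthetic_corpus,
    generate_synthetic_ontology,
    ic_table,
    make_measure,
    mica,
    pairwise_gene_similarity,
    sim_gic,
    sim_ui,
    similarity_matrix,
    teng_similarity,
    term_pair_similarity,
    vector_cosine_similarity,
    wang_similarity,
    wang_term_similarity,
    wis_similarity,
)
from wissim.ontology import AnnotationRecord
from wissim.term_ic import ICTable

from conftest import make_graph


def annotate(pairs):
    return GeneAnnotationSet([AnnotationRecord(g, t) for g, t in pairs])


@pytest.fixture(scope="module")
def setting():
    """A 7-term hand DAG with IC/weight tables and a few annotated genes."""
    g = make_graph([
        ("t2", "t1"), ("t3", "t1"), ("t4", "t2"), ("t5", "t2"),
        ("t6", "t3"), ("t7", "t3"),
    ])
    ics = ic_table(g, ICModelConfig(model="wis"))
    weights = compute_edge_weights(g)
    ann = annotate([
        ("GA", "t4"), ("GA", "t5"),
        ("GB", "t4"), ("GB", "t5"),
        ("GC", "t6"),
        ("GD", "t4"), ("GD", "t6"),
    ])
    return g, ics, weights, ann


class TestWisSimilarity:
    def test_identical_sets_score_one(self, setting):
        g, ics, w, ann = setting
        assert wis_similarity(g, ics, w, ann, "GA", "GB") == pytest.approx(1.0)

    def test_root_only_overlap_scores_zero(self, setting):
        g, ics, w, ann = setting
        # GA closure: {t1,t2,t4,t5}; GC closure: {t1,t3,t6}: intersection {t1}
        assert wis_similarity(g, ics, w, ann, "GA", "GC") == pytest.approx(0.0)

    def test_matches_closed_form_ratio(self, setting):
        from wissim import set_ic_oracle

        g, ics, w, ann = setting
        t1 = g.ancestor_closure(ann.terms("GA"))
        t2 = g.ancestor_closure(ann.terms("GD"))
        want = set_ic_oracle(ics, w, g, t1 & t2) / set_ic_oracle(ics, w, g, t1 | t2)
        assert wis_similarity(g, ics, w, ann, "GA", "GD") == pytest.approx(want)

    def test_unannotated_gene_raises(self, setting):
        g, ics, w, ann = setting
        with pytest.raises(KeyError):
            wis_similarity(g, ics, w, ann, "GA", "NOPE")

    def test_invariant_under_global_ic_rescaling(self, setting):
        g, ics, w, ann = setting
        scaled = ics.scaled(7.3)
        for a, b in [("GA", "GD"), ("GB", "GC"), ("GA", "GB")]:
            assert wis_similarity(g, ics, w, ann, a, b) == pytest.approx(
                wis_similarity(g, scaled, w, ann, a, b), abs=1e-12
            )


class TestTengSimilarity:
    def test_identical_sets(self, setting):
        g, ics, w, ann = setting
        assert teng_similarity(g, ics, w, ann, "GA", "GB") == pytest.approx(1.0)

    def test_chain_closures_telescope(self):
        g = make_graph([("a", "r"), ("b", "a"), ("c", "b")])
        ics = ic_table(g, ICModelConfig(model="wis"))
        w = compute_edge_weights(g)
        ann = annotate([("G1", "b"), ("G2", "c")])
        # unit weighting on chains telescopes to the deepest term's IC
        assert teng_similarity(g, ics, w, ann, "G1", "G2") == pytest.approx(
            ics["b"] / ics["c"]
        )


class TestGroupwiseBaselines:
    def test_simui_arithmetic(self, setting):
        g, _, _, ann = setting
        assert sim_ui(g, ann, "GA", "GB") == 1.0
        # GA closure {t1,t2,t4,t5} vs GD closure {t1,t2,t3,t4,t6}:
        # intersection 3, union 6
        assert sim_ui(g, ann, "GA", "GD") == pytest.approx(3 / 6)

    def test_simgic_matches_bruteforce(self, setting):
        g, ics, _, ann = setting
        t1 = g.ancestor_closure(ann.terms("GA"))
        t2 = g.ancestor_closure(ann.terms("GD"))
        want = sum(ics[t] for t in t1 & t2) / sum(ics[t] for t in t1 | t2)
        assert sim_gic(g, ics, ann, "GA", "GD") == pytest.approx(want)

    def test_simgic_equals_simui_for_flat_ic(self, setting):
        g, _, _, ann = setting
        flat = ICTable({t: 1.0 for t in g.term_ids()}, ICModelConfig())
        for a, b in [("GA", "GD"), ("GB", "GC")]:
            assert sim_gic(g, flat, ann, a, b) == pytest.approx(sim_ui(g, ann, a, b))

    def test_cosine_orthogonal_zero(self, setting):
        g, ics, _, ann = setting
        # overlap only at the root, whose IC is 0 -> zero inner product
        assert vector_cosine_similarity(g, ics, ann, "GA", "GC") == pytest.approx(0.0)

    def test_cosine_identical_printed_vs_standard(self):
        # two-term toy: gene annotated to both leaves of a 3-term star
        g = make_graph([("a", "r"), ("b", "r")])
        ics = ICTable({"r": 0.0, "a": 1.0, "b": 2.0}, ICModelConfig())
        ann = annotate([("G1", "a"), ("G1", "b")])
        norm_sq = 1.0 + 4.0
        printed = vector_cosine_similarity(g, ics, ann, "G1", "G1")
        assert printed == pytest.approx(norm_sq / math.sqrt(2 * norm_sq))
        standard = vector_cosine_similarity(
            g, ics, ann, "G1", "G1", standard_cosine=True
        )
        assert standard == pytest.approx(1.0)


class TestPairwise:
    def test_mica_basics(self, setting):
        g, ics, _, _ = setting
        assert mica(g, ics, "t4", "t4") == "t4"
        # siblings whose only common ancestors are generic: t4 vs t6 -> t1
        assert mica(g, ics, "t4", "t6") == "t1"

    def test_mica_matches_bruteforce(self):
        g = generate_synthetic_ontology(120, max_depth=5, max_parents=3, seed=3)
        ics = ic_table(g, ICModelConfig(model="wis"))
        ids = g.term_ids()
        import random

        rng = random.Random(1)
        for _ in range(25):
            t1, t2 = rng.sample(ids, 2)
            common = g.ancestors(t1, include_self=True) & g.ancestors(
                t2, include_self=True
            )
            best = min(common, key=lambda t: (-ics[t], t))
            assert mica(g, ics, t1, t2) == best

    def test_self_similarity_identities(self, setting):
        g, ics, _, _ = setting
        t = "t4"
        assert term_pair_similarity(g, ics, t, t, "resnik") == pytest.approx(ics[t])
        assert term_pair_similarity(g, ics, t, t, "lin") == pytest.approx(1.0)
        assert term_pair_similarity(g, ics, t, t, "jc") == pytest.approx(1.0)

    def test_lin_zero_ic_terms_score_zero(self, setting):
        g, ics, _, _ = setting
        assert term_pair_similarity(g, ics, "t1", "t1", "lin") == 0.0

    def test_simrel_discounts_by_mica_probability(self, setting):
        g, ics, _, ann = setting
        corpus = build_corpus(g, ann)
        t = "t4"
        lin = term_pair_similarity(g, ics, t, t, "lin")
        rel = term_pair_similarity(g, ics, t, t, "simrel", corpus=corpus)
        assert rel == pytest.approx(lin * (1 - corpus.probability(g, t)))

    def test_resnik_self_pair_is_maximal(self, setting):
        g, ics, _, ann = setting
        terms = sorted(ann.terms("GD"))
        for a in terms:
            for b in terms:
                assert term_pair_similarity(g, ics, a, b, "resnik") <= (
                    term_pair_similarity(g, ics, a, a, "resnik") + 1e-12
                ) or term_pair_similarity(g, ics, b, b, "resnik") >= (
                    term_pair_similarity(g, ics, a, b, "resnik") - 1e-12
                )


class TestCombine:
    def test_single_cell(self):
        for rule in ("avg", "max", "bma"):
            assert combine_pairwise([[0.4]], rule) == pytest.approx(0.4)

    def test_identity_grid(self):
        grid = [[1.0, 0.0], [0.0, 1.0]]
        assert combine_pairwise(grid, "bma") == pytest.approx(1.0)
        assert combine_pairwise(grid, "avg") == pytest.approx(0.5)
        assert combine_pairwise(grid, "max") == pytest.approx(1.0)

    def test_bma_matches_bruteforce_and_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            grid = rng.random((rng.integers(1, 5), rng.integers(1, 5)))
            rows = [max(row) for row in grid]
            cols = [max(col) for col in grid.T]
            want = (sum(rows) + sum(cols)) / (len(rows) + len(cols))
            bma = combine_pairwise(grid, "bma")
            assert bma == pytest.approx(want)
            assert combine_pairwise(grid, "avg") - 1e-12 <= bma
            assert bma <= combine_pairwise(grid, "max") + 1e-12

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            combine_pairwise(np.empty((0, 0)), "bma")


class TestWang:
    def test_term_self_similarity(self, setting):
        g, _, _, _ = setting
        assert wang_term_similarity(g, "t4", "t4") == pytest.approx(1.0)

    def test_chain_hand_values(self):
        # A -> p -> root, fixed is_a weight 0.8:
        # S_A = {A:1, p:0.8, root:0.64}, SV(A)=2.44
        # S_p = {p:1, root:0.8}, SV(p)=1.8
        # shared {p, root}: sim = (0.8+1 + 0.64+0.8) / (2.44+1.8)
        g = make_graph([("p", "root"), ("A", "p")])
        want = (0.8 + 1 + 0.64 + 0.8) / (2.44 + 1.8)
        assert wang_term_similarity(g, "A", "p") == pytest.approx(want)

    def test_two_term_chain(self):
        # single edge A -> p: SV(A) = 1.8, sim(A,p) = (0.8+1)/(1.8+1)
        g = make_graph([("A", "p")])
        assert wang_term_similarity(g, "A", "p") == pytest.approx(1.8 / 2.8)

    @pytest.mark.parametrize("scheme", ["fixed", "eq11"])
    def test_gene_level_contracts(self, scheme):
        g = generate_synthetic_ontology(120, max_depth=5, max_parents=3, seed=6)
        weights = compute_edge_weights(g)
        ann = generate_synthetic_corpus(g, 8, terms_per_gene=(2, 4), seed=6)
        genes = ann.genes
        for a in genes[:4]:
            for b in genes[:4]:
                s_ab = wang_similarity(g, ann, a, b, scheme, weights)
                s_ba = wang_similarity(g, ann, b, a, scheme, weights)
                assert s_ab == pytest.approx(s_ba, abs=1e-12)
                assert 0.0 <= s_ab <= 1.0 + 1e-12
            assert wang_similarity(g, ann, a, a, scheme, weights) == pytest.approx(1.0)


class TestSimilarityMatrix:
    def test_single_gene(self, setting):
        g, ics, w, ann = setting
        spec = MeasureSpec(name="wis")
        fn = make_measure(spec, g, ic=ics, weights=w)
        m = similarity_matrix(fn, ann, genes=["GA"])
        assert m.values.tolist() == [[1.0]]

    def test_symmetry_and_per_pair_consistency(self, setting):
        g, ics, w, ann = setting
        fn = make_measure(MeasureSpec(name="simgic"), g, ic=ics)
        m = similarity_matrix(fn, ann)
        assert np.allclose(m.values, m.values.T)
        for i, a in enumerate(m.genes):
            for j, b in enumerate(m.genes):
                assert m.values[i, j] == pytest.approx(sim_gic(g, ics, ann, a, b))

    def test_unknown_gene_raises(self, setting):
        g, ics, w, ann = setting
        fn = make_measure(MeasureSpec(name="simui"), g)
        with pytest.raises(KeyError):
            similarity_matrix(fn, ann, genes=["GA", "NOPE"])

    def test_tsv_writers(self, tmp_path, setting):
        g, ics, w, ann = setting
        fn = make_measure(MeasureSpec(name="simui"), g)
        m = similarity_matrix(fn, ann, measure="simui")
        m.write_tsv(tmp_path / "wide.tsv")
        m.write_tsv(tmp_path / "long.tsv", long_format=True)
        wide = (tmp_path / "wide.tsv").read_text().splitlines()
        assert wide[1].split("\t")[1:] == m.genes
        long = (tmp_path / "long.tsv").read_text().splitlines()
        n = len(m.genes)
        assert len(long) == 2 + n * (n - 1) // 2
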