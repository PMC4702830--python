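"""Statistical core: hypergeometric tail, BH step-up, PMI, enrichment stages."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from kbforge.errors import DomainError, IntegrityError, UsageError
from kbforge.index import ConceptRef
from kbforge.stats import (Association, EnrichedConcept, bh_adjust,
                           enrich_concepts, hypergeom_sf, pmi,
                           rank_associations, rank_concepts,
                           score_associations)

from _oracles import hypergeom_sf_by_draws, hypergeom_sf_exact


class TestHypergeomSf:
    def test_k_zero_is_one(self):
        assert hypergeom_sf(0, 5, 4, 10) == 1.0

    def test_exhaustive_draw_enumeration_examples(self):
        # N=10, K=5, n=4, k=4: enumerate all C(10,4) draws
        expected = hypergeom_sf_by_draws(4, 5, 4, 10)
        assert expected == Fraction(5, 210)
        assert hypergeom_sf(4, 5, 4, 10) == pytest.approx(float(expected), rel=1e-12)

    def test_closed_form_example(self):
        # N=20, K=10, n=5, k=5 -> C(10,5)/C(20,5)
        assert hypergeom_sf(5, 10, 5, 20) == pytest.approx(252 / 15504, rel=1e-12)

    def test_small_grid_against_exact_oracle(self):
        for N in (1, 4, 9, 14):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        expected = float(hypergeom_sf_exact(k, K, n, N))
                        assert hypergeom_sf(k, K, n, N) == pytest.approx(
                            expected, rel=1e-12), (k, K, n, N)

    def test_monotone_decreasing_in_k(self):
        values = [hypergeom_sf(k, 30, 20, 100) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_pmf_terms_sum_to_one(self):
        for N, K, n in ((100, 30, 20), (1000, 400, 250)):
            ks = np.arange(max(0, K + n - N), min(K, n) + 1)
            total = hypergeom.pmf(ks, N, K, n).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_stable_for_huge_population(self):
        p = hypergeom_sf(500, 10_000, 5_000, 10_000_000)
        assert math.isfinite(p)
        assert 1e-300 <= p <= 1.0  # clipped into the reporting range

    @pytest.mark.parametrize("args", [(-1, 5, 4, 10), (6, 5, 10, 10),
                                      (2, 11, 4, 10), (2, 5, 11, 10)])
    def test_domain_errors(self, args):
        with pytest.raises(DomainError):
            hypergeom_sf(*args)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_computed_step_up_m4(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_hand_computed_step_up_m3(self):
        assert bh_adjust([0.005, 0.04, 0.04]) == pytest.approx(
            [0.015, 0.04, 0.04])

    def test_largest_p_unchanged(self):
        out = bh_adjust([0.2, 0.9, 0.5])
        assert out[1] == pytest.approx(0.9)

    def test_matches_reference_implementation_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(300):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, size=m)
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, rtol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=30), st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        base = bh_adjust(p)
        shuffled = bh_adjust([p[i] for i in idx])
        assert shuffled == pytest.approx([base[i] for i in idx])

    @pytest.mark.parametrize("bad", [[0.0], [1.2], [-0.1], [float("nan")]])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            bh_adjust(bad)


class TestPmi:
    def test_independence_is_zero(self):
        assert pmi(25, 50, 50, 100) == 0.0

    def test_saturation_is_zero(self):
        assert pmi(10, 10, 10, 10) == 0.0

    def test_closed_form(self):
        assert pmi(10, 10, 10, 100) == pytest.approx(math.log2(10))

    def test_symmetric_in_roles(self):
        assert pmi(3, 10, 20, 50) == pmi(3, 20, 10, 50)

    def test_zero_cooccurrence_rejected(self):
        with pytest.raises(DomainError):
            pmi(0, 10, 10, 100)


def _toy_kb_index(kb_pattern, corpus_pattern, small=False):
    """Build an index/kb pair directly from occurrence patterns.

    kb_pattern/corpus_pattern: {concept_id: set of doc ids}; documents are
    synthesized implicitly (no text involved).
    """
    from kbforge.index import GlobalIndex, KnowledgeBase
    all_docs = set()
    for docs in corpus_pattern.values():
        all_docs |= docs
    occurrences = {ConceptRef(c, "Toy"): set(docs)
                   for c, docs in corpus_pattern.items()}
    index = GlobalIndex(occurrences=occurrences, spans={}, doc_ids=all_docs,
                        n_docs=len(all_docs), dictionaries=("Toy",))
    kb_docs = set()
    for docs in kb_pattern.values():
        kb_docs |= docs
    kb_occ = {ConceptRef(c, "Toy"): set(docs)
              for c, docs in kb_pattern.items() if docs}
    kb = KnowledgeBase(name="toy", doc_ids=kb_docs, kb_occurrences=kb_occ,
                       n_docs=len(kb_docs))
    return kb, index


class TestEnrichConcepts:
    def test_concept_in_every_corpus_doc_never_enriched(self):
        corpus = {"A": {f"D{i}" for i in range(100)},
                  "B": {f"D{i}" for i in range(5)}}
        kb_docs = {f"D{i}" for i in range(10)}
        kb_pattern = {c: docs & kb_docs for c, docs in corpus.items()}
        kb, index = _toy_kb_index(kb_pattern, corpus)
        enriched = enrich_concepts(kb, index)
        assert "A" not in {e.concept_id for e in enriched}

    def test_kb_equal_to_corpus_yields_nothing(self):
        corpus = {"A": {"D1", "D2"}, "B": {"D2", "D3"}}
        docs = {"D1", "D2", "D3"}
        kb, index = _toy_kb_index(corpus, corpus)
        kb.doc_ids, kb.n_docs = docs, 3
        assert enrich_concepts(kb, index) == []

    def test_fully_concentrated_concept(self):
        # concept in exactly 5 docs, all inside a 10-doc KB of a 100-doc corpus
        corpus = {"A": {f"D{i}" for i in range(5)},
                  "PAD": {f"D{i}" for i in range(100)}}
        kb_docs = {f"D{i}" for i in range(10)}
        kb, index = _toy_kb_index(
            {c: docs & kb_docs for c, docs in corpus.items()}, corpus)
        kb.doc_ids, kb.n_docs = kb_docs, 10
        enriched = {e.concept_id: e for e in enrich_concepts(kb, index)}
        assert "A" in enriched
        expected = float(hypergeom_sf_exact(5, 5, 10, 100))
        assert enriched["A"].p_value == pytest.approx(expected, rel=1e-12)

    def test_kb_not_subset_of_index_rejected(self):
        kb, index = _toy_kb_index({"A": {"D1"}}, {"A": {"D1"}})
        kb.doc_ids = {"D1", "ALIEN"}
        with pytest.raises(IntegrityError):
            enrich_concepts(kb, index)


def _mk_enriched(cid, name, kb_count, corpus_count, fdr):
    return EnrichedConcept(concept_id=cid, dictionary="Toy", preferred_name=name,
                           kb_count=kb_count, corpus_count=corpus_count,
                           p_value=fdr, fdr=fdr)


class TestRankConcepts:
    def test_alphabetic_case_insensitive(self):
        items = [_mk_enriched("c1", "zeta", 1, 1, 0.01),
                 _mk_enriched("c2", "Alpha", 1, 1, 0.02)]
        assert [e.preferred_name for e in rank_concepts(items, "alphabetic")] == \
               ["Alpha", "zeta"]

    def test_kb_frequency_descending(self):
        items = [_mk_enriched("c1", "a", 3, 9, 0.01),
                 _mk_enriched("c2", "b", 7, 9, 0.02)]
        assert rank_concepts(items, "kb_frequency")[0].concept_id == "c2"

    def test_ties_break_by_concept_id(self):
        items = [_mk_enriched("c2", "b", 3, 9, 0.01),
                 _mk_enriched("c1", "a", 3, 9, 0.01)]
        for mode in ("fdr", "kb_frequency", "corpus_frequency"):
            assert [e.concept_id for e in rank_concepts(items, mode)] == ["c1", "c2"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(UsageError):
            rank_concepts([], "bogus")


class TestScoreAssociations:
    def _enriched_for(self, kb, index):
        return enrich_concepts(kb, index, alpha=1.0)

    def test_non_cooccurring_pair_absent(self):
        corpus = {"A": {"D1"}, "B": {"D2"}, "PAD": {f"P{i}" for i in range(50)}}
        kb_pattern = {"A": {"D1"}, "B": {"D2"}}
        kb, index = _toy_kb_index(kb_pattern, corpus)
        out = score_associations(kb, self._enriched_for(kb, index), index, alpha=1.0)
        assert out == []

    def test_single_shared_doc_pmi_zero(self):
        corpus = {"A": {"D1"}, "B": {"D1"}, "PAD": {f"P{i}" for i in range(50)}}
        kb, index = _toy_kb_index({"A": {"D1"}, "B": {"D1"}}, corpus)
        (assoc,) = score_associations(kb, self._enriched_for(kb, index), index,
                                      alpha=1.0)
        assert assoc.n_ab == 1 and assoc.pmi == 0.0

    def test_pair_ordering_lexicographic(self):
        corpus = {"B": {"D1"}, "A": {"D1"}, "PAD": {f"P{i}" for i in range(20)}}
        kb, index = _toy_kb_index({"B": {"D1"}, "A": {"D1"}}, corpus)
        (assoc,) = score_associations(kb, self._enriched_for(kb, index), index,
                                      alpha=1.0)
        assert assoc.concept_a.concept_id == "A"

    def test_kb_background_mode(self):
        docs_a = {f"D{i}" for i in range(6)}
        docs_b = {f"D{i}" for i in range(3, 9)}
        corpus = {"A": docs_a, "B": docs_b, "PAD": {f"D{i}" for i in range(12)}}
        kb, index = _toy_kb_index(corpus, corpus)
        kb.doc_ids = {f"D{i}" for i in range(12)}
        kb.n_docs = 12
        (assoc,) = [x for x in score_associations(
            kb, self._enriched_for(kb, index), index, alpha=1.0, background="kb")
            if {x.concept_a.concept_id, x.concept_b.concept_id} == {"A", "B"}]
        assert assoc.p_value == pytest.approx(
            float(hypergeom_sf_exact(3, 6, 6, 12)), rel=1e-12)

    def test_rank_by_pmi_and_counts(self):
        a = Association(ConceptRef("A", "T"), ConceptRef("B", "T"),
                        n_ab=2, n_a=4, n_b=4, pmi=1.0, p_value=0.01, fdr=0.02)
        b = Association(ConceptRef("C", "T"), ConceptRef("D", "T"),
                        n_ab=5, n_a=6, n_b=6, pmi=0.5, p_value=0.02, fdr=0.03)
        assert rank_associations([a, b], "pmi")[0] is a
        assert rank_associations([a, b], "n_ab")[0] is b
        assert rank_associations([a, b], "fdr")[0] is a
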