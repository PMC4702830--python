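import pytest

from kbforge.dictionaries import (apply_stoplist, exclude_ambiguous_terms,
                                  load_dictionary, load_stoplist,
                                  normalize_surface, promiscuity_report)
from kbforge.errors import ConfigurationError, FormatError
from kbforge.index import build_global_index

from conftest import make_dictionary, write_dictionary_tsv


class TestLoad:
    def test_rows_grouped_by_concept(self, dictionary_tsv):
        d = load_dictionary(dictionary_tsv)
        assert d.n_concepts == 2
        assert d.n_terms == 3
        assert d.concepts["E1"].terms == {"isocitrate lyase", "icl"}
        assert d.name == "Enzymes" and d.category == "chemicals"

    def test_duplicate_rows_deduplicated_and_reported(self, tmp_path):
        path = tmp_path / "dup.tsv"
        row = ("E1", "Enzymes", "chemicals", "isocitrate lyase",
               "isocitrate lyase", "EC:4.1.3.1")
        write_dictionary_tsv(path, [row, row])
        d = load_dictionary(path)
        assert d.n_terms == 1
        assert d.load_report.duplicates == 1

    def test_column_order_free(self, tmp_path, dictionary_tsv):
        permuted = tmp_path / "permuted.tsv"
        with open(dictionary_tsv, encoding="utf-8") as fh:
            rows = [line.rstrip("\n").split("\t") for line in fh]
        order = [4, 0, 5, 2, 1, 3]  # permute columns, header names preserved
        with open(permuted, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write("\t".join(row[i] for i in order) + "\n")
        a, b = load_dictionary(dictionary_tsv), load_dictionary(permuted)
        assert {c: a.concepts[c].terms for c in a.concepts} == \
               {c: b.concepts[c].terms for c in b.concepts}

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("concept_id\tterm\n1\tfoo\n")
        with pytest.raises(FormatError, match="preferred_name"):
            load_dictionary(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(FormatError):
            load_dictionary(path)

    def test_empty_concept_id_collected_not_fatal(self, tmp_path):
        path = tmp_path / "gap.tsv"
        write_dictionary_tsv(path, [
            ("", "Enzymes", "chemicals", "x", "orphan term", ""),
            ("E1", "Enzymes", "chemicals", "isocitrate lyase",
             "isocitrate lyase", ""),
        ])
        d = load_dictionary(path)
        assert d.n_concepts == 1
        assert d.load_report.n_row_errors == 1

    def test_whitespace_collapsed_and_preferred_name_is_term(self, tmp_path):
        path = tmp_path / "ws.tsv"
        write_dictionary_tsv(path, [
            ("E1", "Enzymes", "chemicals", "malate  synthase",
             "malate   synthase", ""),
        ])
        d = load_dictionary(path)
        assert d.concepts["E1"].terms == {"malate synthase"}
        assert d.concepts["E1"].preferred_name in d.concepts["E1"].terms


class TestNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("  malate   synthase ", "malate synthase"),
        ("beta-lactamase", "beta-lactamase"),
        ("protein ( x )", "protein x"),   # punctuation-only tokens dropped
        ("ﬁeld strain", "field strain"),  # NFKC compatibility form
    ])
    def test_normalize_surface(self, raw, expected):
        assert normalize_surface(raw) == expected


class TestAmbiguity:
    def test_shared_surface_excluded_from_both(self):
        d = make_dictionary("Genes", "genes", {
            "c1": {"ACE", "angiotensin converting enzyme"},
            "c2": {"ACE", "acetylcholinesterase"},
        }, preferred={"c1": "angiotensin converting enzyme",
                      "c2": "acetylcholinesterase"})
        out = exclude_ambiguous_terms(d)
        assert "ACE" not in out.concepts["c1"].terms
        assert "ACE" not in out.concepts["c2"].terms
        assert ("ACE", "ambiguous") in out.excluded_terms
        assert "angiotensin converting enzyme" in out.concepts["c1"].terms
        assert "acetylcholinesterase" in out.concepts["c2"].terms

    def test_no_shared_surfaces_is_identity(self, enzyme_dictionary):
        out = exclude_ambiguous_terms(enzyme_dictionary)
        assert {c: out.concepts[c].terms for c in out.concepts} == \
               {c: enzyme_dictionary.concepts[c].terms
                for c in enzyme_dictionary.concepts}
        assert not out.excluded_terms

    def test_cross_dictionary_sharing_kept(self, enzyme_dictionary):
        other = make_dictionary("Drugs", "chemicals", {"D1": {"isocitrate lyase"}})
        a = exclude_ambiguous_terms(enzyme_dictionary)
        b = exclude_ambiguous_terms(other)
        assert "isocitrate lyase" in a.concepts["E1"].terms
        assert "isocitrate lyase" in b.concepts["D1"].terms

    def test_emptied_concept_kept_but_unmatchable(self):
        d = make_dictionary("Genes", "genes", {"c1": {"abc gene"}, "c2": {"abc gene"}})
        out = exclude_ambiguous_terms(d)
        assert set(out.concepts) == {"c1", "c2"}
        assert out.concepts["c1"].unmatchable and out.concepts["c2"].unmatchable

    def test_idempotent(self):
        d = make_dictionary("Genes", "genes", {
            "c1": {"shared name", "first"}, "c2": {"shared name", "second"},
        })
        once = exclude_ambiguous_terms(d)
        twice = exclude_ambiguous_terms(once)
        assert {c: once.concepts[c].terms for c in once.concepts} == \
               {c: twice.concepts[c].terms for c in twice.concepts}
        assert once.excluded_terms == twice.excluded_terms

    def test_surface_map_is_function_afterwards(self):
        d = make_dictionary("Genes", "genes", {
            "c1": {"shared name", "first"}, "c2": {"Shared Name", "second"},
        })
        out = exclude_ambiguous_terms(d)
        assert all(len(cids) == 1 for cids in out.surface_to_concepts().values())

    def test_no_silent_loss(self):
        d = make_dictionary("Genes", "genes", {
            "c1": {"shared name", "first"}, "c2": {"shared name", "second"},
        })
        out = exclude_ambiguous_terms(d)
        active = out.active_terms()
        excluded = {s for s, _ in out.excluded_terms}
        assert active | excluded == d.active_terms()
        assert not active & excluded


class TestStoplist:
    def test_stopword_removed_case_insensitively(self, enzyme_dictionary):
        d = make_dictionary("Genes", "genes", {"c1": {"the", "real name"}})
        out = apply_stoplist(d, {"The".casefold()})
        assert out.concepts["c1"].terms == {"real name"}
        assert ("the", "stopword") in out.excluded_terms

    def test_empty_stoplist_identity(self, enzyme_dictionary):
        out = apply_stoplist(enzyme_dictionary, set())
        assert out.active_terms() == enzyme_dictionary.active_terms()

    def test_idempotent_for_fixed_stoplist(self):
        d = make_dictionary("Genes", "genes", {"c1": {"protein", "real name"}})
        stop = {"protein"}
        once = apply_stoplist(d, stop)
        twice = apply_stoplist(once, stop)
        assert once.active_terms() == twice.active_terms()
        assert once.excluded_terms == twice.excluded_terms

    def test_load_stoplist_skips_comments(self, tmp_path):
        path = tmp_path / "stop.txt"
        path.write_text("# common words\nprotein\n\nThe\n", encoding="utf-8")
        assert load_stoplist(path) == {"protein", "the"}


class TestPromiscuity:
    def test_ubiquitous_surface_flagged(self, small_corpus, enzyme_dictionary):
        index = build_global_index(small_corpus, [enzyme_dictionary])
        report = promiscuity_report(enzyme_dictionary, index, max_doc_fraction=0.01)
        by_surface = {r.surface: r for r in report}
        assert by_surface["isocitrate lyase"].flagged
        assert by_surface["isocitrate lyase"].doc_frequency == 2

    def test_unseen_surface_zero_not_flagged(self, small_corpus):
        d = make_dictionary("Drugs", "chemicals", {"D1": {"unobtanium"}})
        index = build_global_index(small_corpus, [d])
        (row,) = promiscuity_report(d, index, max_doc_fraction=0.01)
        assert row.doc_frequency == 0 and not row.flagged

    def test_threshold_one_flags_nothing(self, small_corpus, enzyme_dictionary):
        index = build_global_index(small_corpus, [enzyme_dictionary])
        report = promiscuity_report(enzyme_dictionary, index, max_doc_fraction=1.0)
        assert not any(r.flagged for r in report)

    def test_uncovered_dictionary_rejected(self, small_corpus, enzyme_dictionary,
                                           taxa_dictionary):
        index = build_global_index(small_corpus, [enzyme_dictionary])
        with pytest.raises(ConfigurationError):
            promiscuity_report(taxa_dictionary, index)
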